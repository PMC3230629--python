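"""Synthetic transcriptome generation and the genome-wide response pipeline."""

import numpy as np
import pandas as pd
import pytest

from fluxcomp import TranscriptomeConfig, ValidationError, build_state, generate
from fluxcomp.transcriptome import genome_response_distribution, tail_bins
from fluxcomp.translation import density_cap, translation_ultrasensitive


@pytest.fixture(scope="module")
def small_config():
    return TranscriptomeConfig(n_genes=400, seed=7)


@pytest.fixture(scope="module")
def small_table(small_config):
    return generate(small_config)


def test_same_seed_reproduces_table(small_config, small_table):
    again = generate(TranscriptomeConfig(n_genes=400, seed=7))
    pd.testing.assert_frame_equal(small_table, again)
    other = generate(TranscriptomeConfig(n_genes=400, seed=8))
    assert not small_table.equals(other)


def test_generated_table_structure(small_table, small_config):
    cfg = small_config
    assert len(small_table) == cfg.n_genes
    assert small_table["id"].is_unique
    assert (small_table["orf_codons"] >= cfg.L).all()
    assert (small_table["orf_codons"] <= cfg.length_max).all()
    assert (small_table["abundance"] > 0).all()
    occ = small_table["occupancy"].dropna()
    assert ((occ > 0) & (occ < 1)).all()
    assert occ.mean() == pytest.approx(cfg.occupancy_mean, abs=0.05)
    # polysome sizes already respect the density cap
    implied = small_table["polysome_size"] * 100 / small_table["orf_codons"]
    assert (implied <= density_cap(cfg.L) + 1e-12).all()


def test_build_state_reports_and_conservation(small_table, small_config):
    cfg = small_config
    state, report = build_state(small_table, T=cfg.T, L=cfg.L)
    assert report["n_clamped_density"] == int(
        (small_table["density"] > density_cap(cfg.L)).sum()
    )
    assert report["n_filled_occupancy"] == int(small_table["occupancy"].isna().sum())
    bound = float(state.C @ state.P)
    assert bound <= cfg.T
    if report["rescale_factor"] < 1.0:
        # an over-committed draw is rescaled to leave the configured free pool
        assert state.free_ribosomes / cfg.T == pytest.approx(cfg.free_fraction)


def test_occupancy_one_variant_gives_higher_loads(small_table, small_config):
    cfg = small_config
    base, _ = build_state(small_table, T=cfg.T, L=cfg.L)
    ones, _ = build_state(small_table, T=cfg.T, L=cfg.L, occupancy_one=True)
    # before rescaling, occupancy=1 implies P = polysome_size > occ * polysome_size;
    # after the common rescale the saturation *pattern* still differs per gene
    assert not np.allclose(base.saturations, ones.saturations)


def test_distribution_pipeline_identity_and_histogram(small_table, small_config):
    cfg = small_config
    state, _ = build_state(small_table, T=cfg.T, L=cfg.L)
    table, summary = genome_response_distribution(state)
    assert summary["n_genes"] == cfg.n_genes
    coeffs = table["R_T"].to_numpy()
    assert summary["fraction_above_1"] == pytest.approx((coeffs > 1).mean())
    # flag identity: predicate equals coefficient criterion, gene by gene
    assert np.array_equal(
        translation_ultrasensitive(state), coeffs > 1
    )
    assert sum(summary["histogram"]["counts"]) == cfg.n_genes


def test_round_trip_through_tsv(tmp_path, small_table, small_config):
    from fluxcomp.io import write_transcriptome_table
    cfg = small_config
    state, _ = build_state(small_table, T=cfg.T, L=cfg.L)
    path = tmp_path / "genome.tsv"
    write_transcriptome_table(state.to_dataframe(), path, T=cfg.T, L=cfg.L)
    from fluxcomp.io import read_transcriptome_table

    state2, _ = read_transcriptome_table(path)
    t1, s1 = genome_response_distribution(state)
    t2, s2 = genome_response_distribution(state2)
    assert t1["R_T"].to_numpy() == pytest.approx(t2["R_T"].to_numpy(), rel=1e-12)
    assert s1["fraction_above_1"] == s2["fraction_above_1"]


def test_single_gene_genome_never_ultrasensitive():
    state, _ = build_state(
        pd.DataFrame(
            {
                "id": ["only"],
                "abundance": [1.0],
                "orf_codons": [600],
                "polysome_size": [20.0],
                "occupancy": [0.8],
            }
        ),
        T=79.0,
    )
    table, summary = genome_response_distribution(state)
    assert summary["fraction_above_1"] == 0.0
    assert 0 <= table["R_T"].iloc[0] <= 1


def test_lower_occupancy_raises_response_numerator():
    # halving occupancy halves P, raising the free-capacity numerator 1 - s
    df = pd.DataFrame(
        {
            "id": ["a", "b"],
            "abundance": [1.0, 1.0],
            "orf_codons": [240, 240],
            "polysome_size": [10.0, 10.0],
            "occupancy": [0.8, 0.8],
        }
    )
    hi, _ = build_state(df, T=100.0)
    lo, _ = build_state(df.assign(occupancy=[0.4, 0.4]), T=100.0)
    assert np.all(1 - lo.saturations >= 1 - hi.saturations)


def test_tail_bins_sizes_and_determinism():
    rng = np.random.default_rng(0)
    ids = [f"g{i:04d}" for i in range(4621)]
    coeffs = pd.Series(rng.normal(size=4621), index=ids)
    low, high = tail_bins(coeffs, fraction=0.05)
    assert len(low) == len(high) == 231
    assert set(low).isdisjoint(high)
    assert coeffs[low].max() <= coeffs[high].min()
    # all-equal coefficients: bins are the lexicographically first/last ids
    flat = pd.Series(1.0, index=ids)
    lo2, hi2 = tail_bins(flat, fraction=0.05)
    assert lo2 == sorted(ids)[:231]
    assert hi2 == sorted(ids)[-231:]
    # half split on ten genes covers everything once
    ten = pd.Series(range(10), index=[f"x{i}" for i in range(10)])
    l3, h3 = tail_bins(ten, fraction=0.5)
    assert len(l3) == len(h3) == 5 and set(l3) | set(h3) == set(ten.index)
    with pytest.raises(ValidationError):
        tail_bins(ten, fraction=0.7)


def test_infeasible_config_rejected():
    with pytest.raises(ValidationError):
        TranscriptomeConfig(n_genes=0).validate()
    with pytest.raises(ValidationError):
        TranscriptomeConfig(occupancy_mean=1.5).validate()
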