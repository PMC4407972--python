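"""Panel simulation, Li & Stephens expansion, SFS thinning, LD metrics."""

import numpy as np
import pytest
from scipy import stats

from rvpower import panel as pm
from rvpower.errors import InfeasibleSFSError, ParameterError


def test_base_panel_deterministic_and_polymorphic():
    a = pm.simulate_base_panel(10, 2000, seed=3)
    b = pm.simulate_base_panel(10, 2000, seed=3)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert np.array_equal(a.positions, b.positions)
    f = a.allele_freq
    assert np.all((f > 0) & (f < 1))
    assert a.n_haplotypes == 20


def test_base_panel_parameter_errors():
    with pytest.raises(ParameterError):
        pm.simulate_base_panel(1, 2000)
    with pytest.raises(ParameterError):
        pm.simulate_base_panel(10, -5)
    with pytest.raises(ParameterError):
        pm.simulate_base_panel(10, 2000, exon_fraction=0.0)


def test_ld_decays_with_distance():
    p = pm.simulate_base_panel(379, 5000, seed=9)
    prof = pm.ld_profile(p, maf_bins=(0.0, 0.5),
                         distance_bins=np.linspace(0, 5000, 9))
    prof = prof.dropna(subset=["mean_r2"])
    mid = (prof.dist_lo + prof.dist_hi) / 2
    rho, _ = stats.spearmanr(mid, prof.mean_r2)
    assert rho < 0


def test_mosaic_no_mutation_no_recombination_copies_one_row():
    p = pm.simulate_base_panel(20, 1500, seed=1)
    hap = pm.mosaic_haplotype(p, rho=1e-12, theta=1e-12, seed=4)
    matches = np.all(p.haplotypes == hap[None, :], axis=1)
    assert matches.any()


def test_mosaic_zero_theta_matches_copied_template_everywhere():
    p = pm.simulate_base_panel(20, 1500, seed=1)
    hap, path = pm.mosaic_haplotype(p, rho=5e-2, theta=0.0, seed=7,
                                    return_path=True)
    cols = np.arange(p.n_sites)
    assert np.array_equal(hap, p.haplotypes[path, cols])


def test_mosaic_two_templates_used_equally_under_high_rho():
    rng = np.random.default_rng(0)
    haps = rng.integers(0, 2, size=(2, 30)).astype(np.uint8)
    haps[0, 0], haps[1, 0] = 0, 1  # keep both columns polymorphic
    haps[0, 1:] = 1 - haps[1, 1:]
    p = pm.HaplotypePanel(haps, np.arange(30) * 50, np.ones(30, bool),
                          1500, [(0, 1500)])
    _, paths = pm.mosaic_haplotypes(p, 1000, rho=50.0, theta=0.0, seed=2,
                                    return_paths=True)
    frac = paths.mean()
    assert abs(frac - 0.5) < 0.05


def test_mosaic_is_valid_two_color_segmentation():
    """With theta=0 and two templates, every emitted site must equal one of
    the two template alleles (exhaustive path check on a short panel)."""
    rng = np.random.default_rng(3)
    haps = rng.integers(0, 2, size=(2, 18)).astype(np.uint8)
    haps[0] = 1 - haps[1]
    p = pm.HaplotypePanel(haps, np.arange(18) * 80, np.ones(18, bool),
                          1500, [(0, 1500)])
    for s in range(10):
        hap = pm.mosaic_haplotype(p, rho=5.0, theta=0.0, seed=s)
        ok = (hap == haps[0]) | (hap == haps[1])
        assert ok.all()


def test_mosaic_empty_panel_errors():
    with pytest.raises(ParameterError):
        pm._mosaic_batch(np.empty((0, 0), np.uint8), np.empty(0), 1, 1e-3,
                         0.08, np.random.default_rng(0))


def test_expand_arithmetic_and_append_only(base_panel):
    params = pm.ExpansionParams(increment=30, target_n=180)
    big = pm.expand_panel(base_panel, params, seed=8)
    assert big.n_individuals == 180
    assert big.provenance == "expanded"
    # original rows are preserved (up to the minor-allele re-coding flip)
    pos_map = {p: j for j, p in enumerate(big.positions)}
    orig_rows = big.haplotypes[: base_panel.n_haplotypes]
    for j, pos in enumerate(base_panel.positions):
        col = orig_rows[:, pos_map[pos]]
        base_col = base_panel.haplotypes[:, j]
        assert (np.array_equal(col, base_col)
                or np.array_equal(col, 1 - base_col))


def test_expand_rejects_shrinking(base_panel):
    with pytest.raises(ParameterError):
        pm.expand_panel(base_panel, pm.ExpansionParams(target_n=10))


def test_expansion_preserves_common_variant_ld():
    base = pm.simulate_base_panel(379, 3000, seed=21)
    big = pm.expand_panel(base, pm.ExpansionParams(target_n=3000), seed=22)
    bins = np.linspace(0, 3000, 4)
    prof_a = pm.ld_profile(base, maf_bins=(0.05, 0.5), distance_bins=bins)
    prof_b = pm.ld_profile(big, maf_bins=(0.05, 0.5), distance_bins=bins)
    for (_, ra), (_, rb) in zip(prof_a.iterrows(), prof_b.iterrows()):
        if ra.n_pairs > 0 and rb.n_pairs > 0:
            assert abs(ra.mean_r2 - rb.mean_r2) <= 0.05


def test_thin_fixed_point(midi_panel):
    edges = np.array([1e-6, 0.001, 0.01, 0.05, 0.5])
    spec = pm.sfs(midi_panel, edges)
    target = pm.SFSTarget(tuple(edges), tuple(spec.proportion))
    out = pm.thin_to_sfs(midi_panel, target, seed=0)
    assert out.n_sites == midi_panel.n_sites
    assert np.array_equal(out.haplotypes, midi_panel.haplotypes)


def test_thin_zero_mass_above_one_percent(midi_panel):
    target = pm.SFSTarget((1e-6, 0.01, 0.5), (1.0, 0.0))
    out = pm.thin_to_sfs(midi_panel, target, seed=1)
    assert np.all(out.maf < 0.01 + 1e-12)
    assert out.provenance == "thinned"


def test_thin_reduces_sfs_distance():
    base = pm.simulate_base_panel(200, 3000, seed=31)
    big = pm.expand_panel(base, pm.ExpansionParams(target_n=1500), seed=32)
    edges = np.array([1e-6, 5e-4, 5e-3, 0.05, 0.2, 0.5])
    props = np.array([0.30, 0.30, 0.20, 0.12, 0.08])
    target = pm.SFSTarget(tuple(edges), tuple(props))

    def chisq(panel):
        realized = pm.sfs(panel, edges).proportion.to_numpy()
        return np.sum((realized - props) ** 2 / np.where(props > 0, props, 1))

    thinned = pm.thin_to_sfs(big, target, seed=33)
    assert chisq(thinned) <= chisq(big)


def test_thin_infeasible_when_strict(midi_panel):
    target = pm.SFSTarget((1e-6, 0.001, 0.5), (0.5, 0.5),
                          total_per_kb=10_000)
    with pytest.raises(InfeasibleSFSError):
        pm.thin_to_sfs(midi_panel, target, seed=0, strict=True)


def test_sfs_singleton_bin_and_normalization():
    haps = np.zeros((8, 2), np.uint8)
    haps[0, 0] = 1
    haps[:3, 1] = 1
    p = pm.HaplotypePanel(haps, np.array([5, 10]), np.array([True, True]),
                          100, [(0, 100)])
    spec = pm.sfs(p, bins=[1, 2, 3, 4], by="count")
    assert spec["count"].tolist() == [1, 0, 1]
    spec2 = pm.sfs(p, bins=[1e-6, 0.2, 0.5])
    assert spec2.proportion.sum() == pytest.approx(1.0)
    with pytest.raises(ParameterError):
        pm.sfs(p, bins=[1])


def test_subsample_is_rare_depleted(midi_panel):
    """Subsampling the calibrated panel to a much smaller cohort loses rare
    variants faster than common ones (hypergeometric thinning), so the rare
    fraction among segregating sites drops."""
    sub = pm.subsample_individuals(midi_panel, 400, seed=2)
    assert sub.n_individuals == 400
    rare_cut = 0.002

    def rare_fraction(p):
        return float((p.maf < rare_cut).mean())

    assert rare_fraction(sub) < rare_fraction(midi_panel)
    assert sub.n_sites < midi_panel.n_sites


def test_ld_profile_limits():
    haps = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [0, 0], [1, 1]],
                    dtype=np.uint8)
    p = pm.HaplotypePanel(haps, np.array([10, 400]), np.ones(2, bool),
                          1000, [(0, 1000)])
    prof = pm.ld_profile(p, maf_bins=(0.0, 0.5),
                         distance_bins=(0, 1000))
    assert prof.mean_r2.iloc[0] == pytest.approx(1.0)

    rng = np.random.default_rng(5)
    haps = rng.integers(0, 2, size=(2000, 2)).astype(np.uint8)
    p = pm.HaplotypePanel(haps, np.array([10, 400]), np.ones(2, bool),
                          1000, [(0, 1000)])
    prof = pm.ld_profile(p, maf_bins=(0.0, 0.5), distance_bins=(0, 1000))
    assert prof.mean_r2.iloc[0] < 0.01
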