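"""Population statistics: modified Wald CIs, Fisher exact tests,
threshold calibration, spot-count histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

from hibafish.stats import (
    calibrate_threshold,
    condition_summaries,
    fisher_exact_comparison,
    format_percent,
    modified_wald_ci,
    pairwise_comparisons,
    proportion_positive,
    spot_count_histogram,
)


# Published-regime intervals that the add-2/add-4 formula reproduces at the
# printed precision (percent scale; decimals = printed precision).
@pytest.mark.parametrize(
    "x, n, lo, hi, dec",
    [
        (2571, 2695, 94.5, 96.1, 1),
        (2352, 2448, 95.2, 96.8, 1),
        (277, 11753, 2.10, 2.65, 2),
        (343, 11230, 2.75, 3.39, 2),
        (75, 7089, 0.84, 1.33, 2),
        (2508, 2695, 92.0, 94.0, 1),
        (2316, 2448, 93.6, 95.4, 1),
        (45, 11753, 0.29, 0.51, 2),
        (19, 7089, 0.17, 0.42, 2),
        (61, 11230, 0.42, 0.70, 2),
        (53, 7984, 0.51, 0.87, 2),
    ],
)
def test_modified_wald_known_intervals(x, n, lo, hi, dec):
    got_lo, got_hi = modified_wald_ci(x, n)
    assert round(100 * got_lo, dec) == pytest.approx(lo)
    assert round(100 * got_hi, dec) == pytest.approx(hi)


def test_modified_wald_clips_to_unit_interval():
    lo, hi = modified_wald_ci(0, 100)
    assert lo == 0.0 and 0 < hi < 1
    lo, hi = modified_wald_ci(100, 100)
    assert hi == 1.0 and 0 < lo < 1


def test_modified_wald_rejects_bad_input():
    for x, n in [(-1, 10), (11, 10), (0, 0)]:
        with pytest.raises(ValueError):
            modified_wald_ci(x, n)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(x=st_.integers(0, 500), extra=st_.integers(0, 5000))
def test_modified_wald_properties(x, extra):
    """Interval contains the shrunken estimate, stays in [0,1], and narrows
    when n grows at a fixed success fraction."""
    n = x + extra if x + extra > 0 else 1
    lo, hi = modified_wald_ci(x, n)
    p_tilde = (x + 2) / (n + 4)
    assert 0 <= lo <= p_tilde <= hi <= 1
    lo2, hi2 = modified_wald_ci(10 * x, 10 * n)
    assert (hi2 - lo2) <= (hi - lo) + 1e-12


def test_modified_wald_empirical_coverage(rng):
    """~95% nominal coverage holds approximately (>=92%) for rare-event
    proportions at n=1000 over 2000 replicates."""
    n, reps = 1000, 2000
    for p in (0.005, 0.02):
        xs = rng.binomial(n, p, size=reps)
        covered = 0
        for x in np.unique(xs):
            lo, hi = modified_wald_ci(int(x), n)
            covered += int(lo <= p <= hi) * int((xs == x).sum())
        assert covered / reps >= 0.92


def _fisher_enumeration(a, b, c, d):
    """Independent oracle: sum hypergeometric pmf over all tables with the
    same margins whose probability does not exceed the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = sps.hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def test_fisher_reproduces_low_count_comparisons():
    """Rare-translocation 2x2 comparisons land on the published p-values."""
    assert fisher_exact_comparison(7, 7984, 45, 11753).p_value == pytest.approx(
        4.67e-5, rel=2e-3)
    assert fisher_exact_comparison(19, 7089, 61, 11230).p_value == pytest.approx(
        0.0056, rel=5e-3)
    # the stricter positives-vs-negatives table of the same comparison
    assert fisher_exact_comparison(7, 7977, 45, 11708).p_value == pytest.approx(
        2.897e-5, rel=1e-3)


def test_fisher_symmetric_table_is_null():
    res = fisher_exact_comparison(5, 5, 5, 5)
    assert res.p_value == pytest.approx(1.0)
    assert res.fold_change == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(200):
        a, b, c, d = rng.integers(0, 16, size=4)
        if a + b == 0 or c + d == 0:
            continue
        got = fisher_exact_comparison(int(a), int(b), int(c), int(d)).p_value
        assert got == pytest.approx(_fisher_enumeration(a, b, c, d), rel=1e-8)


def test_fisher_invariant_under_row_and_column_swaps(rng):
    for _ in range(50):
        a, b, c, d = (int(v) for v in rng.integers(1, 20, size=4))
        p = fisher_exact_comparison(a, b, c, d).p_value
        assert fisher_exact_comparison(c, d, a, b).p_value == pytest.approx(p)
        assert fisher_exact_comparison(b, a, d, c).p_value == pytest.approx(p)


def test_fisher_fold_change_undefined_at_zero_baseline():
    res = fisher_exact_comparison(0, 100, 5, 95)
    assert res.fold_change is None
    assert 0 <= res.p_value <= 1


def test_calibrate_threshold_simple_and_contaminated():
    assert calibrate_threshold([0.2, 0.5, 1.0] * 100, coverage=0.998) == 1
    # a 0.2% far tail does not move the 99.8% coverage point
    d = np.concatenate([np.full(4990, 1.0), np.full(10, 0.5), np.full(2, 10.0)])
    t_clean = calibrate_threshold(d[:-2], coverage=0.998)
    assert calibrate_threshold(d, coverage=0.998) == t_clean == 1
    with pytest.raises(ValueError):
        calibrate_threshold([])


def test_calibrate_threshold_monotone_in_coverage(rng):
    d = rng.rayleigh(1.0, size=5000)
    ts = [calibrate_threshold(d, c) for c in (0.5, 0.9, 0.99, 0.998, 1.0)]
    assert ts == sorted(ts)


def test_proportion_positive_and_formatting():
    df = pd.DataFrame(
        {"qc_pass": [True] * 10 + [False],
         "breakage_positive": [True] * 3 + [False] * 7 + [True],
         "translocation_positive": [False] * 10 + [True]}
    )
    x, n, p = proportion_positive(df, "breakage")
    assert (x, n) == (3, 10) and p == pytest.approx(0.3)
    # QC-failed nuclei never count, even if flagged positive
    assert proportion_positive(df, "translocation")[0] == 0
    assert format_percent(53 / 7984) == "0.66%"
    assert format_percent(2571 / 2695) == "95.4%"
    assert format_percent(277 / 11753) == "2.36%"
    assert format_percent(7 / 7984) == "0.088%"
    assert format_percent(0.0) == "0.00%"


def test_spot_count_histogram():
    freq = spot_count_histogram([2] * 10)
    assert dict(freq) == {2: 1.0}
    assert spot_count_histogram([]).empty
    freq = spot_count_histogram([0, 0, 1, 3, 3, 3])
    assert freq.loc[0] == pytest.approx(1 / 3)  # zero-spot bin included
    assert freq.sum() == pytest.approx(1.0)


def test_spot_count_histogram_modes_for_mixed_ploidy():
    """A population carrying mostly three gene-A and two gene-B alleles has
    spot-count modes at 3 (Green/Red) and 2 (FarRed)."""
    import hibafish as hf
    from hibafish import simulate as sim
    from hibafish.config import CellModel

    mixture = [(CellModel(name="tri", n_alleles_A=3, n_alleles_B=2), 0.7),
               (CellModel(name="di", n_alleles_A=2, n_alleles_B=2), 0.2),
               (CellModel(name="tetra", n_alleles_A=4, n_alleles_B=3), 0.1)]
    gt = sim.simulate_ground_truth(
        mixture, 200, rng=np.random.default_rng(41),
        imaging=hf.ImagingConfig(field_shape_px=(1024, 1024)))
    counts = gt.spots.groupby(["cell_id", "channel"]).size().unstack(fill_value=0)
    for ch, mode in (("Green", 3), ("Red", 3), ("FarRed", 2)):
        freq = spot_count_histogram(counts[ch])
        assert freq.idxmax() == mode


def test_condition_tables_roundtrip():
    mk = lambda pos, n: pd.DataFrame(
        {"qc_pass": [True] * n,
         "breakage_positive": [True] * pos + [False] * (n - pos),
         "translocation_positive": [False] * n})
    summary = condition_summaries({"UN": mk(5, 500), "IR": mk(25, 500)})
    assert len(summary) == 4  # 2 conditions x 2 event classes
    assert (summary["ci_low"] <= summary["proportion"]).all()
    assert (summary["proportion"] <= summary["ci_high"]).all()
    comp = pairwise_comparisons(summary)
    br = comp[comp["event_class"] == "breakage"].iloc[0]
    assert br["p_value"] < 0.01 and br["fold_change"] == pytest.approx(5.0)
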