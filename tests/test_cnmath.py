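import itertools

import numpy as np
import pandas as pd
import pytest

from cohortviz import (GScoreParams, PurityPloidy, blacklist,
                       count_breakpoints, gscore, loh, mix, purify_baf,
                       purify_log2r, purify_r, purity_from_tp53, ssv_filter)
from cohortviz.cnmath import gscore_weight


# ---------------------------------------------------------------------------
# Purity approximation


@pytest.mark.parametrize("cn, vaf, expected", [
    (2, 1.0, 1.0),    # pure tumor, homozygous mutation
    (2, 0.5, 0.5),
    (4, 0.5, 1 / 3),
])
def test_purity_from_tp53_examples(cn, vaf, expected):
    assert purity_from_tp53(cn, vaf) == pytest.approx(expected, abs=1e-15)


def test_purity_from_tp53_errors():
    with pytest.raises(ValueError):
        purity_from_tp53(2, 0)
    with pytest.raises(ValueError):
        purity_from_tp53(0, 0.5)


def test_purity_recovery_identity():
    """VAF simulated from the homozygous-mutation mixture recovers purity."""
    for p in np.linspace(0.05, 1.0, 20):
        for cn in (1, 2, 3, 4, 6):
            vaf = p * cn / (p * cn + 2 * (1 - p))
            assert abs(purity_from_tp53(cn, vaf) - p) < 1e-12


# ---------------------------------------------------------------------------
# Purification


def test_purify_r_examples():
    assert purify_r(1.7, PurityPloidy(1.0, 3.0)) == pytest.approx(1.7)
    for pp in (PurityPloidy(0.3, 2.0), PurityPloidy(0.9, 4.1)):
        assert purify_r(1.0, pp) == pytest.approx(1.0)  # neutral invariance
    assert purify_r(1.5, PurityPloidy(0.5, 2.0)) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        purify_r(-1.0, PurityPloidy(0.5, 2.0))
    with pytest.raises(ValueError):
        PurityPloidy(0.0, 2.0)


def test_purify_baf_examples():
    pp1 = PurityPloidy(1.0, 2.0)
    for b in (0.0, 0.2, 0.5, 0.9):
        assert purify_baf(b, 1.3, pp1) == pytest.approx(b, abs=1e-12)
    for pp, r in ((PurityPloidy(0.4, 2.0), 0.7), (PurityPloidy(0.8, 3.3), 2.0)):
        assert purify_baf(0.5, r, pp) == pytest.approx(0.5)  # symmetry fixpoint
    assert purify_baf(0.25, 1.0, PurityPloidy(0.5, 2.0)) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        purify_baf(1.5, 1.0, pp1)


def test_purified_baf_clamped_to_unit_interval():
    # low purity + extreme baf can push the raw formula outside [0, 1]
    v = purify_baf(0.0, 0.6, PurityPloidy(0.2, 2.0))
    assert 0.0 <= v <= 1.0


@pytest.mark.parametrize("baf, expected", [
    (0.5, 0.0), (0.0, 1.0), (1.0, 1.0), (0.25, 0.5),
])
def test_loh_endpoints(baf, expected):
    assert loh(baf) == expected


def test_loh_domain():
    with pytest.raises(ValueError):
        loh(1.2)


def test_loh_of_purified_baf_symmetric():
    pp = PurityPloidy(0.6, 2.4)
    assert loh(purify_baf(0.5, 1.2, pp)) == 0.0
    for b in (0.1, 0.25, 0.4):
        assert loh(purify_baf(b, 1.2, pp)) == pytest.approx(
            loh(purify_baf(1 - b, 1.2, pp)), abs=1e-12)


def test_mix_neutral_fixpoint_and_identity():
    r, b = mix(1.0, 0.5, PurityPloidy(0.37, 3.1))
    assert (r, b) == (pytest.approx(1.0), pytest.approx(0.5))
    r, b = mix(1.8, 0.2, PurityPloidy(1.0, 2.0))
    assert (r, b) == (pytest.approx(1.8), pytest.approx(0.2))


def test_purification_roundtrip_grid():
    """purify(mix(x)) = x to 1e-9 over a >=1000-point parameter grid."""
    purities = np.linspace(0.1, 1.0, 7)
    ploidies = np.linspace(1.5, 6.0, 6)
    rs = np.linspace(0.25, 4.0, 6)
    bafs = np.linspace(0.0, 0.5, 5)
    count = 0
    worst = 0.0
    for p, psi, r, b in itertools.product(purities, ploidies, rs, bafs):
        pp = PurityPloidy(p, psi)
        obs_r, obs_b = mix(r, b, pp)
        worst = max(worst,
                    abs(purify_r(obs_r, pp) - r),
                    abs(purify_baf(obs_b, obs_r, pp) - b))
        count += 1
    assert count >= 1000
    assert worst < 1e-9


def test_purify_log2r_wrapper():
    pp = PurityPloidy(0.5, 2.0)
    assert 2 ** purify_log2r(np.log2(1.5), pp) == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# G-score


def brute_force_gscore(segments, n_samples, thr=0.7, cap=2.5, genome_bp=2000):
    """Per-base oracle over a small linear genome, per chromosome."""
    profiles = {1: {}, -1: {}}
    for chrom in {s["chrom"] for s in segments}:
        for sign in (1, -1):
            per_base = np.zeros(genome_bp)
            for s in (x for x in segments if x["chrom"] == chrom):
                v = s["value"]
                if abs(v) <= thr or np.sign(v) != sign:
                    continue
                per_base[s["start"]:s["end"]] += min(abs(v), cap)
            profiles[sign][chrom] = per_base / n_samples
    return profiles


def to_per_base(profile_df, genome_bp=2000):
    out = {}
    for chrom, grp in profile_df.groupby("chrom"):
        arr = np.zeros(genome_bp)
        for _, row in grp.iterrows():
            arr[int(row["start"]):int(row["end"])] = row["gscore"]
        out[chrom] = arr
    return out


def seg_df(segments):
    return pd.DataFrame([{**s, "purified_log2r": s["value"]} for s in segments])


def test_gscore_single_segment():
    amp, dele = gscore(seg_df([{"sample": "s1", "chrom": "c", "start": 0,
                                "end": 1000, "value": 1.0}]), n_samples=1)
    assert amp.to_dict("records") == [
        {"chrom": "c", "start": 0, "end": 1000, "gscore": 1.0}]
    assert dele.empty


def test_gscore_threshold_and_clamp():
    below = seg_df([{"sample": "s1", "chrom": "c", "start": 0, "end": 100,
                     "value": 0.5}])
    amp, dele = gscore(below, n_samples=1)
    assert amp.empty and dele.empty
    assert gscore_weight(0.5) == 0.0
    assert gscore_weight(3.0) == 2.5  # clamped
    assert gscore_weight(-3.0) == 2.5
    assert gscore_weight(0.7) == 0.0  # strict > keeps a segment
    amp, _ = gscore(seg_df([{"sample": "s1", "chrom": "c", "start": 0,
                             "end": 500, "value": 3.0}]), n_samples=2)
    assert amp["gscore"].tolist() == [1.25]  # 2.5 / 2 samples


def test_gscore_matches_per_base_oracle_random_cohorts():
    rng = np.random.default_rng(11)
    for _ in range(50):
        segments = []
        n_samples = int(rng.integers(1, 5))
        for si in range(n_samples):
            for chrom in ("c1", "c2"):
                pos = 0
                while pos < 1900:
                    end = pos + int(rng.integers(50, 600))
                    end = min(end, 2000)
                    segments.append({
                        "sample": f"s{si}", "chrom": chrom,
                        "start": pos, "end": end,
                        "value": float(rng.uniform(-3.5, 3.5))})
                    pos = end
        amp, dele = gscore(seg_df(segments), n_samples=n_samples)
        oracle = brute_force_gscore(segments, n_samples)
        for profile, sign in ((amp, 1), (dele, -1)):
            got = to_per_base(profile)
            for chrom in ("c1", "c2"):
                np.testing.assert_allclose(
                    got.get(chrom, np.zeros(2000)), oracle[sign][chrom],
                    atol=1e-9)
        for profile in (amp, dele):
            if not profile.empty:
                assert (profile["gscore"] >= 0).all()
                assert (profile["gscore"] <= 2.5).all()


def test_gscore_errors():
    with pytest.raises(ValueError):
        gscore(seg_df([]), n_samples=0)
    with pytest.raises(ValueError):
        GScoreParams(inclusion_threshold=3.0, cap=2.5)


def test_gscore_binned_output():
    amp, _ = gscore(seg_df([{"sample": "s1", "chrom": "c", "start": 0,
                             "end": 150, "value": 1.0}]),
                    n_samples=1, params=GScoreParams(bin_size=100))
    assert amp.to_dict("records") == [
        {"chrom": "c", "start": 0, "end": 100, "gscore": 1.0},
        {"chrom": "c", "start": 100, "end": 200, "gscore": 0.5}]


# ---------------------------------------------------------------------------
# Breakpoints, blacklist, SSV filter


def test_count_breakpoints():
    def segs(spec):
        return pd.DataFrame([{"sample": "s", "chrom": c, "start": a, "end": b}
                             for c, a, b in spec])
    assert count_breakpoints(segs([("c1", 0, 10), ("c2", 0, 10)])) == 0
    assert count_breakpoints(segs([("c1", 0, 5), ("c1", 5, 8), ("c1", 8, 10)])) == 2
    assert count_breakpoints(segs([("c1", 0, 5), ("c1", 5, 8), ("c1", 8, 10),
                                   ("c2", 0, 5), ("c2", 5, 10)])) == 3
    with pytest.raises(ValueError, match="overlap"):
        count_breakpoints(segs([("c1", 0, 6), ("c1", 5, 10)]))


def test_blacklist_rule():
    panel = pd.DataFrame(
        [[0.3, -0.3, 0.3, 0.0],    # 3 exceeders -> in
         [0.3, 0.3, 0.0, 0.0],     # 2 exceeders -> out
         [0.2, 0.2, 0.2, 0.2],     # exactly 0.2 does not count (strict >)
         [-0.5, 0.21, 0.9, 0.0]],  # 3 exceeders -> in
        index=["r1", "r2", "r3", "r4"])
    assert blacklist(panel) == ["r1", "r4"]
    with pytest.raises(ValueError):
        blacklist(panel, min_samples=5)


def test_ssv_filter_boundaries():
    ssvs = pd.DataFrame({
        "cadd": [9.9, 10.0, 1.0, np.nan],
        "clinvar_pathogenic": [False, False, True, False],
    })
    kept = ssv_filter(ssvs)
    assert kept["cadd"].fillna(-1).tolist() == [10.0, 1.0]
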