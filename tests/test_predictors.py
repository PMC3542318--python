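import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amylcons.model import NO_SCORE, ProteinSequence
from amylcons.predictors import (
    ADAPTER_METHODS,
    METHOD_IDS,
    NATIVE_METHODS,
    apply_method_threshold,
    get_config,
    get_registry,
    run_aggrescan,
    run_all,
    run_amyloidogenic_pattern,
    run_average_packing_density,
    run_beta_contiguity,
    run_waltz_pssm,
)
from amylcons.predictors.native import aggrescan_window
from amylcons.predictors.registry import RegistryError

from oracles import NATIVE_ORACLES, bsc_y, waltz_window_score

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

seq_strategy = st.text(alphabet=STANDARD_AA, min_size=1, max_size=100)


# ---- registry ---------------------------------------------------------------


def test_registry_scales_cover_standard_alphabet():
    reg = get_registry()
    for scale in reg.scales.values():
        assert set(scale.values) == set(STANDARD_AA)


def test_registry_min_lengths_match_published_limits():
    assert get_config("pafig").min_length == 6
    assert get_config("netcssp").min_length == 7
    assert get_config("amylmut").min_length == 20
    assert get_config("pattern").min_length == 6
    assert get_config("waltz").min_length == 6
    assert get_config("apd").min_length == 5


def test_registry_unknown_method():
    with pytest.raises(RegistryError):
        get_config("nosuchmethod")


def test_pssm_has_all_positions_and_residues():
    pssm = get_registry().pssms["hexapeptide_ph7"]
    assert pssm.width == 6
    assert pssm.scores.shape == (6, 20)
    assert np.all(np.isfinite(pssm.scores))


# ---- amyloidogenic pattern --------------------------------------------------


def test_pattern_stviie_fully_hit():
    result = run_amyloidogenic_pattern(ProteinSequence("p", "STVIIE"))
    assert result.status == "ok"
    assert result.hits.tolist() == [True] * 6
    assert result.hit_regions() == [(1, 6)]


def test_pattern_polyproline_no_hits():
    result = run_amyloidogenic_pattern(ProteinSequence("p", "PPPPPP"))
    assert not result.hits.any()


def test_pattern_short_sequence_is_ok_with_zero_hits():
    result = run_amyloidogenic_pattern(ProteinSequence("p", "STVIE"))
    assert result.status == "ok"
    assert not result.hits.any()


def test_pattern_overlapping_matches_union():
    # STVIIE + shifted second match: windows overlap, hits union
    result = run_amyloidogenic_pattern(ProteinSequence("p", "ASTVIIEFA"))
    assert result.hits.tolist() == NATIVE_ORACLES["pattern"]("ASTVIIEFA")


# ---- average packing density ------------------------------------------------


def low_high_apd_residues():
    values = get_registry().scales["packing_density"].values
    low = next(aa for aa, v in values.items() if v <= 21.4)
    high = next(aa for aa, v in values.items() if v > 21.4)
    return low, high


def test_apd_homopolymer_below_threshold():
    low, _ = low_high_apd_residues()
    result = run_average_packing_density(ProteinSequence("p", low * 20))
    assert result.status == "ok"
    assert not result.hits.any()


def test_apd_homopolymer_above_threshold():
    _, high = low_high_apd_residues()
    result = run_average_packing_density(ProteinSequence("p", high * 20))
    assert result.hits.all()


def test_apd_too_short():
    result = run_average_packing_density(ProteinSequence("p", "AAAA"))
    assert result.status == "skipped_too_short"
    assert not result.hits.any()


def test_apd_scores_are_max_covering_window_mean():
    seq = ProteinSequence("p", "ILVFMKDEST" * 3)
    result = run_average_packing_density(seq)
    values = get_registry().scales["packing_density"].values
    window = 5
    for i in range(seq.length):
        covering = [
            sum(values[aa] for aa in seq.residues[s : s + window]) / window
            for s in range(max(0, i - window + 1), min(i, seq.length - window) + 1)
        ]
        assert result.scores[i] == pytest.approx(max(covering))


# ---- beta-strand contiguity -------------------------------------------------


def test_bsc_low_propensity_homopolymer_zero():
    # E has the lowest beta propensity (0.37 << 1.2)
    result = run_beta_contiguity(ProteinSequence("p", "E" * 30))
    assert result.status == "ok"
    assert np.all(result.scores == 0.0)
    assert not result.hits.any()


def test_bsc_y_nondecreasing_in_qualifying_windows():
    # V-homopolymer: every added residue adds qualifying windows; y grows
    y10 = max(run_beta_contiguity(ProteinSequence("p", "V" * 10)).scores)
    y20 = max(run_beta_contiguity(ProteinSequence("p", "V" * 20)).scores)
    assert y20 >= y10


def test_bsc_too_short():
    assert run_beta_contiguity(ProteinSequence("p", "VVV")).status == "skipped_too_short"


def test_bsc_matches_bruteforce_on_random_50mer(rng):
    residues = "".join(rng.choice(list(STANDARD_AA), size=50))
    result = run_beta_contiguity(ProteinSequence("p", residues))
    assert np.allclose(result.scores, bsc_y(residues))
    assert result.hits.tolist() == NATIVE_ORACLES["bsc"](residues)


# ---- aggrescan --------------------------------------------------------------


def test_aggrescan_window_length_rule():
    rule = get_config("aggrescan").params["window_rule"]
    assert aggrescan_window(50, rule) == 5
    assert aggrescan_window(75, rule) == 5
    assert aggrescan_window(76, rule) == 7
    assert aggrescan_window(175, rule) == 7
    assert aggrescan_window(300, rule) == 9
    assert aggrescan_window(301, rule) == 11


def test_aggrescan_homopolymer_below_threshold():
    result = run_aggrescan(ProteinSequence("p", "D" * 30))  # a3v(D) = -1.836
    assert not result.hits.any()


def test_aggrescan_hit_locality_under_extension():
    core = "DDDDDIIIIIDDDDD"
    r1 = run_aggrescan(ProteinSequence("p", core))
    r2 = run_aggrescan(ProteinSequence("p", core + "D" * 10))
    assert r1.hits.tolist() == r2.hits.tolist()[: len(core)]


# ---- waltz PSSM -------------------------------------------------------------


def test_waltz_homopolymer_score_is_position_sum():
    pssm = get_registry().pssms["hexapeptide_ph7"]
    col = STANDARD_AA.index("A")
    expected = float(pssm.scores[:, col].sum())
    assert pssm.window_score("AAAAAA") == pytest.approx(expected)


def test_waltz_too_short():
    assert run_waltz_pssm(ProteinSequence("p", "AAAAA")).status == "skipped_too_short"


def test_waltz_raising_threshold_only_removes_hits(random_sequences):
    for seq in random_sequences[:30]:
        loose = run_waltz_pssm(seq, threshold=79.0).hits
        strict = run_waltz_pssm(seq, threshold=92.0).hits
        assert not np.any(strict & ~loose)


def test_waltz_random_30mer_matches_bruteforce(rng):
    residues = "".join(rng.choice(list(STANDARD_AA), size=30))
    result = run_waltz_pssm(ProteinSequence("p", residues))
    assert result.hits.tolist() == NATIVE_ORACLES["waltz"](residues)
    # per-residue score is the max covering window score
    for i in range(30):
        covering = [
            waltz_window_score(residues[s : s + 6])
            for s in range(max(0, i - 5), min(i, 24) + 1)
        ]
        assert result.scores[i] == pytest.approx(max(covering))


# ---- non-standard residues --------------------------------------------------


@pytest.mark.parametrize("runner", [run_average_packing_density, run_aggrescan,
                                    run_waltz_pssm, run_beta_contiguity])
def test_nonstandard_residues_never_hit(runner):
    result = runner(ProteinSequence("p", "X" * 30))
    assert result.status == "ok"
    assert not result.hits.any()


# ---- adapter thresholding ---------------------------------------------------


def _adapter(method, n, **columns):
    seq = ProteinSequence("p", "A" * n)
    cols = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    return apply_method_threshold(get_config(method), cols, seq)


def test_tango_boundary_strictly_above_5():
    result = _adapter("tango", 3, beta=[0.0, 4.99, 5.01])
    assert result.hits.tolist() == [False, False, True]
    result = _adapter("tango", 1, beta=[5.00])
    assert result.hits.tolist() == [False]


def test_hce_boundary_strictly_below_minus_27():
    result = _adapter("hce", 6, energy=[-26.99, -27.00, -27.01, 0.0, -30.0, -27.0])
    assert result.hits.tolist() == [False, False, True, False, True, False]


def test_netcssp_requires_both_conditions():
    # HbP = pbeta/phelix must be strictly > 1 AND pbeta strictly > 6
    result = _adapter(
        "netcssp", 7,
        pbeta=[7, 7, 6.5, 5, 8, 6, 7.2],
        phelix=[7, 6, 6.0, 1, 7, 1, 7.1],
    )
    #        hbp: 1, 1.17, 1.08, 5, 1.14, 6, 1.014
    assert result.hits.tolist() == [False, True, True, False, True, False, True]


def test_pafig_reliability_index_inclusive_at_7():
    result = _adapter("pafig", 6, ri=[6, 7, 8, 0, 9, 6.99])
    assert result.hits.tolist() == [False, True, True, False, True, False]


def test_adapter_missing_column_is_external_missing():
    result = _adapter("netcssp", 7, pbeta=[7] * 7)  # phelix absent
    assert result.status == "external_missing"
    assert not result.hits.any()


def test_adapter_no_score_positions_never_hit():
    result = _adapter("tango", 5, beta=[10.0, np.nan, 10.0])  # short vector padded
    assert result.hits.tolist() == [True, False, True, False, False]
    assert np.isnan(result.scores[3])


def test_adapter_too_short():
    result = _adapter("amylmut", 10, score=[1.0] * 10)
    assert result.status == "skipped_too_short"
    assert not result.hits.any()


# ---- run_all ----------------------------------------------------------------


def test_run_all_native_selection_on_50mer(rng):
    residues = "".join(rng.choice(list(STANDARD_AA), size=50))
    results = run_all(ProteinSequence("p", residues), set(NATIVE_METHODS))
    assert [r.method for r in results] == sorted(NATIVE_METHODS)
    assert all(r.status == "ok" for r in results)


def test_run_all_short_sequence_skips_length_limited_methods():
    results = run_all(ProteinSequence("p", "AAAAA"))  # 5 residues, all 11
    status = {r.method: r.status for r in results}
    for method in ("pattern", "waltz", "pafig", "netcssp", "amylmut"):
        assert status[method] == "skipped_too_short"
    assert status["apd"] == "ok"


def test_run_all_order_is_canonical():
    seq = ProteinSequence("p", "A" * 30)
    a = run_all(seq, {"waltz", "apd", "pattern"})
    b = run_all(seq, {"pattern", "waltz", "apd"})
    assert [r.method for r in a] == [r.method for r in b] == ["apd", "pattern", "waltz"]


def test_run_all_rejects_empty_or_unknown_selection():
    seq = ProteinSequence("p", "A" * 30)
    with pytest.raises(ValueError):
        run_all(seq, set())
    with pytest.raises(ValueError):
        run_all(seq, {"bogus"})


def test_run_all_adapter_without_scores_is_external_missing():
    seq = ProteinSequence("p", "A" * 30)
    results = run_all(seq, {"apd", "tango"})
    status = {r.method: r.status for r in results}
    assert status["tango"] == "external_missing"
    assert status["apd"] == "ok"


# ---- properties -------------------------------------------------------------


@settings(max_examples=60, deadline=None)
@given(seq_strategy)
def test_native_predictors_match_bruteforce_oracle(residues):
    seq = ProteinSequence("p", residues)
    runners = {
        "pattern": run_amyloidogenic_pattern,
        "apd": run_average_packing_density,
        "aggrescan": run_aggrescan,
        "waltz": run_waltz_pssm,
        "bsc": run_beta_contiguity,
    }
    for method, runner in runners.items():
        result = runner(seq)
        if result.status != "ok":
            assert not result.hits.any()
            continue
        assert result.hits.tolist() == NATIVE_ORACLES[method](residues), method


@settings(max_examples=40, deadline=None)
@given(seq_strategy.filter(lambda s: len(s) >= 6), st.integers(0, 94))
def test_window_locality_under_point_mutation(residues, pos):
    """Mutating residue i only changes hits within window-1 residues of i."""
    pos = min(pos, len(residues) - 1)
    mutated = residues[:pos] + ("G" if residues[pos] != "G" else "A") + residues[pos + 1 :]
    before = run_waltz_pssm(ProteinSequence("p", residues))
    after = run_waltz_pssm(ProteinSequence("p", mutated))
    if before.status != "ok":
        return
    changed = np.nonzero(before.hits != after.hits)[0]
    assert all(abs(int(i) - pos) <= 5 for i in changed)


def test_determinism():
    seq = ProteinSequence("p", "STVIIEDEKRSGQNAD" * 3)
    a = run_all(seq, set(NATIVE_METHODS))
    b = run_all(seq, set(NATIVE_METHODS))
    for r1, r2 in zip(a, b):
        assert r1.hits.tolist() == r2.hits.tolist()
        assert np.allclose(r1.scores, r2.scores, equal_nan=True)


def test_method_result_invariant_hits_imply_real_scores(random_sequences):
    for seq in random_sequences[:50]:
        for result in run_all(seq, set(NATIVE_METHODS)):
            if result.hits.any():
                assert np.all(np.isfinite(result.scores[result.hits]))
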