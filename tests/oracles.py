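"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's vectorized/window machinery: plain
per-window Python loops over the same packaged data tables, so any indexing
or aggregation bug in the implementation cannot also hide here.
"""

import math

from amylcons.predictors import get_config, get_registry

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def _scale_value(scale_name: str, aa: str):
    values = get_registry().scales[scale_name].values
    return values.get(aa)  # None for non-standard residues


def _window_mean(residues: str, scale_name: str):
    vals = [_scale_value(scale_name, aa) for aa in residues]
    if any(v is None for v in vals):
        return None
    return sum(vals) / len(vals)


def pattern_hits(residues: str) -> list[bool]:
    pattern = get_registry().patterns["hexapeptide"]
    n = len(residues)
    hits = [False] * n
    for start in range(n - pattern.width + 1):
        window = residues[start : start + pattern.width]
        if all(aa in pattern.allowed[p] for p, aa in enumerate(window)):
            for i in range(start, start + pattern.width):
                hits[i] = True
    return hits


def apd_hits(residues: str) -> list[bool]:
    config = get_config("apd")
    window, cutoff = int(config.window), float(config.params["threshold"])
    n = len(residues)
    hits = [False] * n
    for start in range(n - window + 1):
        mean = _window_mean(residues[start : start + window], "packing_density")
        if mean is not None and mean > cutoff:
            for i in range(start, start + window):
                hits[i] = True
    return hits


def aggrescan_hits(residues: str) -> list[bool]:
    config = get_config("aggrescan")
    n = len(residues)
    window = None
    for max_length, w in config.params["window_rule"]:
        if max_length is None or n <= max_length:
            window = int(w)
            break
    cutoff = float(config.params["hotspot_threshold"])
    hits = [False] * n
    for start in range(n - window + 1):
        mean = _window_mean(residues[start : start + window], "aggrescan_a3v")
        if mean is not None and mean > cutoff:
            for i in range(start, start + window):
                hits[i] = True
    return hits


def waltz_window_score(window: str):
    pssm = get_registry().pssms["hexapeptide_ph7"]
    total = 0.0
    for p, aa in enumerate(window):
        if aa not in STANDARD_AA:
            return None
        total += pssm.scores[p, STANDARD_AA.index(aa)]
    return total


def waltz_hits(residues: str, threshold: float = 79.0) -> list[bool]:
    n = len(residues)
    hits = [False] * n
    for start in range(n - 6 + 1):
        score = waltz_window_score(residues[start : start + 6])
        if score is not None and score >= threshold:
            for i in range(start, start + 6):
                hits[i] = True
    return hits


def bsc_y(residues: str) -> list[float]:
    """Cumulative beta-contiguity score by explicit window enumeration."""
    config = get_config("bsc")
    lo, hi = int(config.params["min_window"]), int(config.params["max_window"])
    wthr = float(config.params["window_threshold"])
    top_k = config.params.get("top_k")
    n = len(residues)
    candidates = []
    for window in range(lo, min(hi, n) + 1):
        for start in range(n - window + 1):
            mean = _window_mean(residues[start : start + window], "beta_propensity")
            if mean is not None and mean >= wthr:
                candidates.append((mean, start, window))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    if top_k is not None:
        candidates = candidates[: int(top_k)]
    y = [0.0] * n
    for mean, start, window in candidates:
        for i in range(start, start + window):
            y[i] += mean
    return y


def bsc_hits(residues: str) -> list[bool]:
    cutoff = float(get_config("bsc").params["y_threshold"])
    return [y > cutoff for y in bsc_y(residues)]


def confusion(predicted, truth_mask):
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth_mask):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def mcc(tp, tn, fp, fn):
    denom = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


NATIVE_ORACLES = {
    "pattern": pattern_hits,
    "apd": apd_hits,
    "aggrescan": aggrescan_hits,
    "waltz": waltz_hits,
    "bsc": bsc_hits,
}
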