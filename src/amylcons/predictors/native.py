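"""Native per-residue predictors: hexapeptide pattern matching, packing-
density and aggregation-propensity sliding windows, cumulative beta-strand
contiguity, and PSSM scoring of hexapeptide windows.

Shared semantics:

* Only full-length windows are scored (no truncated edge windows).
* A residue is a hit if ANY qualifying window covers it (union semantics).
* Windows containing a non-standard residue (X/B/Z/U/O) are unscorable and
  never qualify.
* ``scores`` report, per residue, the best (max) window statistic among the
  windows covering it — except for beta-strand contiguity, whose score is
  the cumulative sum ``y`` itself.
"""

from __future__ import annotations

import numpy as np

from ..model import NO_SCORE, MethodResult, ProteinSequence
from .registry import compare, get_config, get_registry

__all__ = [
    "run_amyloidogenic_pattern",
    "run_average_packing_density",
    "run_beta_contiguity",
    "run_aggrescan",
    "run_waltz_pssm",
]


def _too_short(method: str, seq: ProteinSequence, config) -> MethodResult:
    n = seq.length
    return MethodResult(
        method=method,
        sequence_id=seq.id,
        scores=np.full(n, NO_SCORE),
        hits=np.zeros(n, dtype=bool),
        config=config,
        status="skipped_too_short",
    )


def _window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Mean of each full window; NaN where any position lacks a value."""
    # cumulative-sum convolution would be fine too; n is small, keep it plain
    n = len(values)
    means = np.full(n - window + 1, np.nan)
    for start in range(n - window + 1):
        chunk = values[start : start + window]
        if not np.any(np.isnan(chunk)):
            means[start] = chunk.mean()
    return means


def _spread_windows(
    n: int, window: int, stats: np.ndarray, qualifying: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Union window hits onto residues; per-residue score = max covering stat."""
    hits = np.zeros(n, dtype=bool)
    scores = np.full(n, NO_SCORE)
    for start, stat in enumerate(stats):
        if np.isnan(stat):
            continue
        sl = slice(start, start + window)
        scores[sl] = np.fmax(scores[sl], stat)
        if qualifying[start]:
            hits[sl] = True
    return scores, hits


def run_amyloidogenic_pattern(seq: ProteinSequence) -> MethodResult:
    """Flag every residue covered by a window matching the six-position
    amyloidogenic pattern; sequences shorter than the pattern yield zero
    hits with status ``ok`` (pattern matching is vacuous, not an error)."""
    config = get_config("pattern")
    pattern = get_registry().patterns[config.params["pattern"]]
    n = seq.length
    hits = np.zeros(n, dtype=bool)
    scores = np.zeros(n)
    for start in range(n - pattern.width + 1):
        if pattern.matches(seq.residues[start : start + pattern.width]):
            hits[start : start + pattern.width] = True
    scores[hits] = 1.0
    return MethodResult("pattern", seq.id, scores, hits, config)


def run_average_packing_density(seq: ProteinSequence) -> MethodResult:
    config = get_config("apd")
    if seq.length < config.min_length:
        return _too_short("apd", seq, config)
    scale = get_registry().scales[config.params["scale"]]
    window = int(config.window)
    means = _window_means(scale.vector(seq.residues), window)
    qualifying = compare(
        means, config.params["comparator"], float(config.params["threshold"])
    )
    scores, hits = _spread_windows(seq.length, window, means, qualifying)
    return MethodResult("apd", seq.id, scores, hits, config)


def run_beta_contiguity(seq: ProteinSequence) -> MethodResult:
    """Cumulative sliding-average beta-strand propensity.

    All windows of length ``min_window..max_window`` are scored by their mean
    propensity; windows at or above the window threshold qualify.  The
    ``top_k`` highest-mean qualifying windows each add their mean to every
    residue they cover, giving the cumulative score ``y``; residues with
    ``y`` strictly above the y-threshold are hits.
    """
    config = get_config("bsc")
    if seq.length < config.min_length:
        return _too_short("bsc", seq, config)
    scale = get_registry().scales[config.params["scale"]]
    # plain sequential sums: window ranking near the top_k cutoff must not
    # depend on numpy's pairwise-summation rounding
    values = [scale.values.get(aa) for aa in seq.residues]
    lo = int(config.params["min_window"])
    hi = int(config.params["max_window"])
    wthr = float(config.params["window_threshold"])
    top_k = config.params.get("top_k")
    candidates: list[tuple[float, int, int]] = []  # (mean, start, window)
    for window in range(lo, min(hi, seq.length) + 1):
        for start in range(seq.length - window + 1):
            chunk = values[start : start + window]
            if any(v is None for v in chunk):
                continue
            mean = sum(chunk) / window
            if mean >= wthr:
                candidates.append((mean, start, window))
    # deterministic ranking: mean desc, then position/length for ties
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    if top_k is not None:
        candidates = candidates[: int(top_k)]
    y = np.zeros(seq.length)
    for mean, start, window in candidates:
        y[start : start + window] += mean
    hits = y > float(config.params["y_threshold"])
    return MethodResult("bsc", seq.id, y, hits, config)


def aggrescan_window(length: int, rule=None) -> int:
    """Window length as a function of sequence length (packaged rule)."""
    if rule is None:
        rule = get_config("aggrescan").params["window_rule"]
    for max_length, window in rule:
        if max_length is None or length <= max_length:
            return int(window)
    raise ValueError("window rule has no catch-all entry")


def run_aggrescan(seq: ProteinSequence) -> MethodResult:
    config = get_config("aggrescan")
    if seq.length < config.min_length:
        return _too_short("aggrescan", seq, config)
    scale = get_registry().scales[config.params["scale"]]
    window = aggrescan_window(seq.length, config.params["window_rule"])
    means = _window_means(scale.vector(seq.residues), window)
    qualifying = compare(
        means,
        config.params["comparator"],
        float(config.params["hotspot_threshold"]),
    )
    scores, hits = _spread_windows(seq.length, window, means, qualifying)
    return MethodResult("aggrescan", seq.id, scores, hits, config)


def run_waltz_pssm(seq: ProteinSequence, threshold: float | None = None) -> MethodResult:
    """Score every hexapeptide window against the packaged PSSM; windows at
    or above the threshold mark all six residues as hits."""
    config = get_config("waltz")
    if seq.length < config.min_length:
        return _too_short("waltz", seq, config)
    pssm = get_registry().pssms[config.params["pssm"]]
    if threshold is None:
        threshold = float(config.params["threshold"])
    n = seq.length
    width = pssm.width
    stats = np.array(
        [pssm.window_score(seq.residues[s : s + width]) for s in range(n - width + 1)]
    )
    qualifying = compare(stats, config.params["comparator"], threshold)
    scores, hits = _spread_windows(n, width, stats, qualifying)
    return MethodResult("waltz", seq.id, scores, hits, config)
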