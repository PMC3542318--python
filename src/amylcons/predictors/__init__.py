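"""Component predictors: five native methods plus six threshold adapters."""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ..model import NO_SCORE, MethodResult, ProteinSequence
from .adapters import apply_method_threshold
from .native import (
    run_aggrescan,
    run_amyloidogenic_pattern,
    run_average_packing_density,
    run_beta_contiguity,
    run_waltz_pssm,
)
from .registry import (
    ADAPTER_METHODS,
    METHOD_IDS,
    NATIVE_METHODS,
    MethodConfig,
    PropensityScale,
    PSSMProfile,
    get_config,
    get_registry,
)

__all__ = [
    "METHOD_IDS",
    "NATIVE_METHODS",
    "ADAPTER_METHODS",
    "MethodConfig",
    "PropensityScale",
    "PSSMProfile",
    "get_config",
    "get_registry",
    "apply_method_threshold",
    "run_amyloidogenic_pattern",
    "run_average_packing_density",
    "run_beta_contiguity",
    "run_aggrescan",
    "run_waltz_pssm",
    "run_all",
]

_NATIVE_RUNNERS = {
    "pattern": run_amyloidogenic_pattern,
    "apd": run_average_packing_density,
    "bsc": run_beta_contiguity,
    "aggrescan": run_aggrescan,
    "waltz": run_waltz_pssm,
}


def run_all(
    seq: ProteinSequence,
    selection: set[str] | None = None,
    external_scores: Mapping[str, Mapping[str, np.ndarray]] | None = None,
) -> list[MethodResult]:
    """Run every selected method on one sequence, in canonical order.

    ``selection`` defaults to all eleven methods.  ``external_scores`` maps
    adapter method id to its score-column table for this sequence; selected
    adapters without scores return status ``external_missing``.
    """
    if selection is None:
        selection = set(METHOD_IDS)
    if not selection:
        raise ValueError("empty method selection")
    unknown = selection - set(METHOD_IDS)
    if unknown:
        raise ValueError(f"unknown method(s): {', '.join(sorted(unknown))}")
    external_scores = external_scores or {}
    results: list[MethodResult] = []
    for method_id in METHOD_IDS:  # canonical order, not selection order
        if method_id not in selection:
            continue
        config = get_config(method_id)
        if method_id in _NATIVE_RUNNERS:
            # run_all uniformly reports skipped_too_short below min_length,
            # including for the pattern method (which, called directly, is
            # simply vacuous on short sequences).
            if seq.length < config.min_length:
                results.append(
                    MethodResult(
                        method_id,
                        seq.id,
                        np.full(seq.length, NO_SCORE),
                        np.zeros(seq.length, dtype=bool),
                        config,
                        status="skipped_too_short",
                    )
                )
            else:
                results.append(_NATIVE_RUNNERS[method_id](seq))
        else:
            results.append(
                apply_method_threshold(
                    config, external_scores.get(method_id, {}), seq
                )
            )
    return results
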