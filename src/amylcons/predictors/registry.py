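"""Method registry: packaged scales, the hexapeptide pattern and PSSM, and
per-method configuration (thresholds, windows, minimum lengths).

Every numeric table ships as a versioned data file whose SHA-256 is pinned
in ``methods.yaml`` and verified at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from ..model import STANDARD_AA, AmylconsError

#: Canonical method identifiers, in canonical (report) order.
METHOD_IDS = (
    "aggrescan",
    "amylmut",
    "apd",
    "bsc",
    "hce",
    "netcssp",
    "pafig",
    "pattern",
    "secstr",
    "tango",
    "waltz",
)

NATIVE_METHODS = ("aggrescan", "apd", "bsc", "pattern", "waltz")
ADAPTER_METHODS = ("amylmut", "hce", "netcssp", "pafig", "secstr", "tango")


class RegistryError(AmylconsError):
    pass


@dataclass(frozen=True)
class PropensityScale:
    """A residue -> value map loaded from a packaged, checksummed TSV."""

    name: str
    source: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise RegistryError(
                f"scale {self.name!r}: must cover exactly the 20 standard residues"
            )

    def vector(self, residues: str) -> np.ndarray:
        """Per-residue values; NaN for non-standard residues."""
        return np.array(
            [self.values.get(aa, np.nan) for aa in residues], dtype=float
        )


@dataclass(frozen=True)
class PSSMProfile:
    """Position x residue scoring matrix; window score is the entry sum."""

    name: str
    width: int
    scores: np.ndarray  # shape (width, 20), columns ordered as STANDARD_AA
    score_transform: str = "sum of per-position entries over the window"

    def __post_init__(self) -> None:
        if self.scores.shape != (self.width, len(STANDARD_AA)):
            raise RegistryError(
                f"PSSM {self.name!r}: expected shape ({self.width}, 20)"
            )

    def window_score(self, window: str) -> float:
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != {self.width}")
        total = 0.0
        for pos, aa in enumerate(window):
            col = STANDARD_AA.find(aa)
            if col < 0:
                return float("nan")
            total += self.scores[pos, col]
        return total


@dataclass(frozen=True)
class SequencePattern:
    """Per-position allowed/forbidden residue sets over a fixed width."""

    name: str
    width: int
    allowed: tuple[frozenset, ...]  # matching set per position (standard AAs)

    def matches(self, window: str) -> bool:
        if len(window) != self.width:
            return False
        return all(aa in self.allowed[p] for p, aa in enumerate(window))


@dataclass(frozen=True)
class MethodConfig:
    """Everything needed to run one method: rule, windows, length limit."""

    method: str
    kind: str  # native | adapter
    min_length: int
    threshold_rule: tuple[tuple[str, str, float], ...] = ()
    window: object = None
    params: Mapping[str, object] = field(default_factory=dict)


_COMPARATORS = {
    "gt": lambda x, c: x > c,
    "ge": lambda x, c: x >= c,
    "lt": lambda x, c: x < c,
    "le": lambda x, c: x <= c,
}


def compare(values: np.ndarray, comparator: str, cutoff: float) -> np.ndarray:
    """Vectorized threshold comparison; NaN (no score) never satisfies."""
    if comparator not in _COMPARATORS:
        raise RegistryError(f"unknown comparator {comparator!r}")
    with np.errstate(invalid="ignore"):
        return _COMPARATORS[comparator](np.asarray(values, dtype=float), cutoff)


def _data_bytes(filename: str) -> bytes:
    return (resources.files("amylcons") / "data" / filename).read_bytes()


def _verify_checksum(filename: str, expected: str) -> bytes:
    raw = _data_bytes(filename)
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise RegistryError(
            f"data file {filename!r}: checksum mismatch "
            f"(expected {expected[:12]}..., got {digest[:12]}...)"
        )
    return raw


def _parse_kv_tsv(raw: bytes) -> dict[str, float]:
    values: dict[str, float] = {}
    for line in raw.decode().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        values[aa] = float(value)
    return values


def _parse_pssm_tsv(raw: bytes, width: int) -> np.ndarray:
    rows: dict[int, list[float]] = {}
    order: list[str] | None = None
    for line in raw.decode().splitlines():
        if line.startswith("# pos\t"):
            order = line[len("# pos\t") :].split("\t")
            continue
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        rows[int(fields[0])] = [float(v) for v in fields[1:]]
    if order is None or sorted(order) != sorted(STANDARD_AA):
        raise RegistryError("PSSM file: missing or incomplete residue header")
    matrix = np.empty((width, len(STANDARD_AA)))
    for pos in range(1, width + 1):
        if pos not in rows:
            raise RegistryError(f"PSSM file: missing position {pos}")
        for aa, value in zip(order, rows[pos]):
            matrix[pos - 1, STANDARD_AA.index(aa)] = value
    return matrix


def _parse_pattern_txt(raw: bytes) -> tuple[frozenset, ...]:
    standard = frozenset(STANDARD_AA)
    per_pos: dict[int, frozenset] = {}
    for line in raw.decode().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos_s, mode, residues = line.split("\t")
        pos = int(pos_s)
        if mode == "allow":
            per_pos[pos] = frozenset(residues)
        elif mode == "forbid":
            per_pos[pos] = standard - frozenset(residues)
        else:
            raise RegistryError(f"pattern file: unknown mode {mode!r}")
    width = max(per_pos)
    if sorted(per_pos) != list(range(1, width + 1)):
        raise RegistryError("pattern file: positions must be contiguous from 1")
    return tuple(per_pos[p] for p in range(1, width + 1))


class Registry:
    """Loaded method registry; constructed once and cached."""

    def __init__(self) -> None:
        spec = yaml.safe_load(_data_bytes("methods.yaml"))
        self._spec = spec
        self.configs: dict[str, MethodConfig] = {}
        self.scales: dict[str, PropensityScale] = {}
        self.pssms: dict[str, PSSMProfile] = {}
        self.patterns: dict[str, SequencePattern] = {}
        for method_id in METHOD_IDS:
            entry = spec["methods"][method_id]
            rule = tuple(
                (col, cmp_, float(cut)) for col, cmp_, cut in entry.get("rule", [])
            )
            self.configs[method_id] = MethodConfig(
                method=method_id,
                kind=entry["kind"],
                min_length=int(entry["min_length"]),
                threshold_rule=rule,
                window=entry.get("window"),
                params={
                    k: v
                    for k, v in entry.items()
                    if k not in {"kind", "min_length", "rule", "window"}
                },
            )
        for name, entry in spec.get("scales", {}).items():
            raw = _verify_checksum(entry["file"], entry["sha256"])
            self.scales[name] = PropensityScale(
                name=name, source=entry.get("source", ""), values=_parse_kv_tsv(raw)
            )
        for name, entry in spec.get("pssms", {}).items():
            raw = _verify_checksum(entry["file"], entry["sha256"])
            self.pssms[name] = PSSMProfile(
                name=name,
                width=int(entry["width"]),
                scores=_parse_pssm_tsv(raw, int(entry["width"])),
            )
        for name, entry in spec.get("patterns", {}).items():
            raw = _verify_checksum(entry["file"], entry["sha256"])
            allowed = _parse_pattern_txt(raw)
            self.patterns[name] = SequencePattern(
                name=name, width=len(allowed), allowed=allowed
            )


_registry: Registry | None = None


def get_registry() -> Registry:
    global _registry
    if _registry is None:
        _registry = Registry()
    return _registry


def get_config(method_id: str) -> MethodConfig:
    try:
        return get_registry().configs[method_id]
    except KeyError:
        raise RegistryError(
            f"unknown method {method_id!r}; valid: {', '.join(METHOD_IDS)}"
        ) from None
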