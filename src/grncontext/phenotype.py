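"""Logic-phenotype classification of four-environment expression vectors.

The GRN output is read in four environments, in the fixed order
(none, IPTG, aTc, IPTG+aTc).  Two classifiers are provided:

- the *model* classifier thresholds normalized cI: the network output is
  ON when normalized cI falls below tau (cI represses the reporter), and
- the *experimental* classifier applies the two threefold rules to
  positive fluorescence means: OFF requires at least threefold repression
  relative to the highest state, and every ON value must in turn exceed
  threefold the largest OFF value; when the separation fails the strain is
  labelled AMBIGUOUS rather than forced into a class.

A phenotype is named by its ON/OFF pattern; the handful of patterns with
standard logic-gate names (NOR, NOT_aTc, NOT_IPTG, ALL_ON, ALL_OFF) use
them, the rest render as e.g. ``ON-OFF-ON-OFF``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import STATE_NAMES

__all__ = [
    "AMBIGUOUS",
    "TruthTable",
    "logic_name",
    "logic_bits",
    "bits_to_string",
    "string_to_bits",
    "classify_model",
    "classify_experimental",
    "threshold_sweep",
    "fold_sweep",
]

AMBIGUOUS = "AMBIGUOUS"

#: ON/OFF pattern -> canonical gate name, state order (none, IPTG, aTc, both).
_NAMED_PATTERNS = {
    (True, True, True, True): "ALL_ON",
    (False, False, False, False): "ALL_OFF",
    (True, False, False, False): "NOR",
    (True, True, False, False): "NOT_aTc",
    (True, False, True, False): "NOT_IPTG",
}
_PATTERN_BY_NAME = {v: k for k, v in _NAMED_PATTERNS.items()}


def _coerce_bits(bits: Sequence[bool]) -> tuple[bool, bool, bool, bool]:
    out = tuple(bool(b) for b in bits)
    if len(out) != 4:
        raise ValueError(f"need 4 output states, got {len(out)}")
    return out  # type: ignore[return-value]


def logic_name(bits: Sequence[bool]) -> str:
    """Name of the 4-state ON/OFF pattern (bijective over the 16 patterns)."""
    key = _coerce_bits(bits)
    if key in _NAMED_PATTERNS:
        return _NAMED_PATTERNS[key]
    return "-".join("ON" if b else "OFF" for b in key)


def logic_bits(label: str) -> tuple[bool, bool, bool, bool]:
    """Inverse of :func:`logic_name`; also accepts ``"1100"`` bit strings."""
    if label in _PATTERN_BY_NAME:
        return _PATTERN_BY_NAME[label]
    if set(label) <= {"0", "1"} and len(label) == 4:
        return string_to_bits(label)
    parts = label.split("-")
    if len(parts) == 4 and all(p in ("ON", "OFF") for p in parts):
        return tuple(p == "ON" for p in parts)  # type: ignore[return-value]
    raise ValueError(f"unknown logic label {label!r}")


def bits_to_string(bits: Sequence[bool]) -> str:
    return "".join("1" if b else "0" for b in _coerce_bits(bits))


def string_to_bits(s: str) -> tuple[bool, bool, bool, bool]:
    if len(s) != 4 or set(s) - {"0", "1"}:
        raise ValueError(f"bad bit string {s!r}")
    return tuple(ch == "1" for ch in s)  # type: ignore[return-value]


@dataclass(frozen=True)
class TruthTable:
    """Raw output vector, its max-normalized form, and the ON/OFF calls."""

    raw: np.ndarray
    normalized: np.ndarray
    outputs: tuple[bool, bool, bool, bool]

    @property
    def label(self) -> str:
        return logic_name(self.outputs)

    @classmethod
    def from_raw(cls, c_values: Sequence[float], tau: float = 0.4) -> "TruthTable":
        raw = np.asarray(c_values, dtype=float)
        if raw.shape != (4,):
            raise ValueError("expected 4 values in canonical state order")
        if np.any(raw < 0):
            raise ValueError("negative expression values")
        if not 0.0 < tau < 1.0:
            raise ValueError("tau must be in (0, 1)")
        peak = float(raw.max())
        if peak < 1e-12:
            # no repressor output at all: the reporter is on everywhere
            normalized = np.zeros(4)
            outputs = (True, True, True, True)
        else:
            normalized = raw / peak
            outputs = tuple(bool(v < tau) for v in normalized)
        return cls(raw, normalized, outputs)  # type: ignore[arg-type]


def classify_model(c_values: Sequence[float], tau: float = 0.4) -> str:
    """Label from model cI values: ON iff normalized cI < tau."""
    return TruthTable.from_raw(c_values, tau=tau).label


def classify_experimental(yfp_means: Sequence[float], fold: float = 3.0) -> str:
    """Label from replicate-mean fluorescence using the two threefold rules."""
    v = np.asarray(yfp_means, dtype=float)
    if v.shape != (4,):
        raise ValueError("expected 4 condition means in canonical state order")
    if np.any(v <= 0):
        raise ValueError("fluorescence means must be positive")
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    peak = v.max()
    on = v > peak / fold
    if on.all():
        return "ALL_ON"
    if v[on].min() < fold * v[~on].max():
        return AMBIGUOUS
    return logic_name(on)


def _sweep(
    vectors: Mapping[str, Sequence[float]],
    thresholds: Iterable[float],
    classify,
    colname: str,
) -> pd.DataFrame:
    rows = []
    for th in thresholds:
        counts: dict[str, int] = {}
        for vec in vectors.values():
            lbl = classify(vec, th)
            counts[lbl] = counts.get(lbl, 0) + 1
        for lbl in sorted(counts):
            rows.append({colname: th, "label": lbl, "count": counts[lbl]})
    return pd.DataFrame(rows, columns=[colname, "label", "count"])


def threshold_sweep(
    c_vectors_by_arrangement: Mapping[str, Sequence[float]],
    taus: Iterable[float],
) -> pd.DataFrame:
    """Model-label tallies as the threshold tau varies: tidy (tau, label, count)."""
    return _sweep(c_vectors_by_arrangement, taus, classify_model, "tau")


def fold_sweep(
    means_by_arrangement: Mapping[str, Sequence[float]],
    folds: Iterable[float],
) -> pd.DataFrame:
    """Experimental-label tallies as the fold threshold varies."""
    return _sweep(means_by_arrangement, folds, classify_experimental, "fold")


def truth_table_frame(labels_to_raw: Mapping[str, Sequence[float]], tau: float = 0.4) -> pd.DataFrame:
    """Tidy table of raw/normalized values and calls, one row per (arrangement, state)."""
    rows = []
    for arr_label, raw in labels_to_raw.items():
        tt = TruthTable.from_raw(raw, tau=tau)
        for i, state in enumerate(STATE_NAMES):
            rows.append(
                {
                    "arrangement": arr_label,
                    "state": state,
                    "cI": tt.raw[i],
                    "cI_normalized": tt.normalized[i],
                    "output": "ON" if tt.outputs[i] else "OFF",
                    "label": tt.label,
                }
            )
    return pd.DataFrame(rows)
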