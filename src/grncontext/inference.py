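"""Phenotype prediction over all arrangements and (K, mu) grid-search inference.

The model fits *logic classes*, not quantitative fluorescence: a candidate
(K, mu) is scored by how many observed arrangement labels its predictions
reproduce, and the admissible region is the set of grid cells attaining
the maximal agreement count (the data leave a region, not a point; partial
agreement is expected and reported, never hidden).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arrangements import Arrangement, enumerate_arrangements, pair_id, parse_label
from .dynamics import ModelParameters, readthrough_config, truth_table_grid
from .phenotype import classify_model, logic_bits

__all__ = [
    "GridResult",
    "default_K_grid",
    "default_mu_grid",
    "predict_all",
    "grid_search",
    "compare_predictions",
    "validate_observed",
]


def default_K_grid(n: int = 25) -> np.ndarray:
    """Logarithmic K grid over [1e-3, 10] (package default; overridable)."""
    return np.logspace(-3, 1, n)


def default_mu_grid(n: int = 21) -> np.ndarray:
    """Linear mu grid over [0, 1]."""
    return np.linspace(0.0, 1.0, n)


def _as_arrangement(x) -> Arrangement:
    return x if isinstance(x, Arrangement) else parse_label(x)


def validate_observed(observed: pd.DataFrame) -> pd.DataFrame:
    """Check an observed-phenotype table: parseable labels, one row each."""
    if observed.empty:
        raise ValueError("observed table is empty")
    for col in ("arrangement", "label"):
        if col not in observed.columns:
            raise ValueError(f"observed table lacks required column {col!r}")
    dupes = observed["arrangement"][observed["arrangement"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate arrangement keys: {sorted(set(dupes))}")
    for lbl in observed["arrangement"]:
        parse_label(lbl)  # raises LabelError naming the token
    return observed


def predict_all(
    arrangements: Iterable[Arrangement] | None = None,
    params: ModelParameters | None = None,
) -> pd.DataFrame:
    """Model phenotype per arrangement at fixed parameters.

    Returns one row per arrangement with the label and the four raw cI
    values.  Deterministic; arrangements sharing a read-through wiring
    (e.g. whole-cassette flips) share a cached truth table.
    """
    params = params or ModelParameters()
    arrangements = (
        list(arrangements) if arrangements is not None else enumerate_arrangements()
    )
    cache: dict = {}
    rows = []
    for a in arrangements:
        cfg = readthrough_config(a, chain=params.chain_readthrough)
        if cfg not in cache:
            cache[cfg] = truth_table_grid(cfg, params.K, params.mu, params).ravel()
        cI = cache[cfg]
        rows.append(
            {
                "arrangement": a.label,
                "pair": pair_id(a),
                "label": classify_model(cI, tau=params.tau),
                "cI_none": cI[0],
                "cI_IPTG": cI[1],
                "cI_aTc": cI[2],
                "cI_both": cI[3],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GridResult:
    """Agreement landscape of a (K, mu) grid search."""

    K_grid: np.ndarray
    mu_grid: np.ndarray
    agreement: np.ndarray  # shape (len(K_grid), len(mu_grid)), int counts
    n_observed: int
    tau: float

    @property
    def max_agreement(self) -> int:
        return int(self.agreement.max())

    @property
    def admissible(self) -> np.ndarray:
        return self.agreement == self.max_agreement

    def argmax_cells(self) -> list[tuple[float, float]]:
        """Admissible (K, mu) cells in deterministic (K-, then mu-) order."""
        iK, imu = np.nonzero(self.admissible)
        return [(float(self.K_grid[i]), float(self.mu_grid[j])) for i, j in zip(iK, imu)]

    def to_frame(self) -> pd.DataFrame:
        Kv, mv = np.meshgrid(self.K_grid, self.mu_grid, indexing="ij")
        return pd.DataFrame(
            {
                "K": Kv.ravel(),
                "mu": mv.ravel(),
                "agreement": self.agreement.ravel(),
                "admissible": self.admissible.ravel(),
            }
        )

    def summary(self) -> dict:
        return {
            "n_observed": self.n_observed,
            "max_agreement": self.max_agreement,
            "n_admissible_cells": int(self.admissible.sum()),
            "tau": self.tau,
            "argmax_cells": [
                {"K": K, "mu": mu} for K, mu in self.argmax_cells()
            ],
        }


def _pattern_codes(cI4: np.ndarray, tau: float) -> np.ndarray:
    """ON/OFF pattern codes (state-0 bit most significant) per grid cell."""
    peak = cI4.max(axis=0)
    safe = np.where(peak > 1e-12, peak, 1.0)
    norm = cI4 / safe
    bits = norm < tau
    bits = np.where(peak > 1e-12, bits, True)
    code = np.zeros(cI4.shape[1:], dtype=int)
    for i in range(4):
        code = code * 2 + bits[i].astype(int)
    return code


def _label_code(label: str) -> int:
    bits = logic_bits(label)
    code = 0
    for b in bits:
        code = code * 2 + int(b)
    return code


def grid_search(
    observed: pd.DataFrame,
    K_grid: Sequence[float] | None = None,
    mu_grid: Sequence[float] | None = None,
    tau: float = 0.4,
    base_params: ModelParameters | None = None,
    arrangements: Mapping[str, Arrangement] | None = None,
) -> GridResult:
    """Agreement between predicted and observed labels over a (K, mu) grid.

    ``observed`` needs columns ``arrangement`` (label text) and ``label``
    (logic class).  Rows labelled AMBIGUOUS can never match a prediction
    and simply cap the attainable agreement.  ``arrangements`` may map
    label text to explicit :class:`Arrangement` objects (e.g. terminator
    variants); plain labels are parsed with default T1 junctions.
    """
    validate_observed(observed)
    K = np.asarray(default_K_grid() if K_grid is None else K_grid, dtype=float)
    mu = np.asarray(default_mu_grid() if mu_grid is None else mu_grid, dtype=float)
    if K.size == 0 or mu.size == 0 or np.any(K <= 0):
        raise ValueError("grids must be non-empty and K strictly positive")
    params = (base_params or ModelParameters()).with_(tau=tau)

    Kv = K[:, None]
    muv = mu[None, :]
    agreement = np.zeros((K.size, mu.size), dtype=int)
    code_cache: dict = {}
    for _, row in observed.iterrows():
        a = (
            arrangements[row["arrangement"]]
            if arrangements and row["arrangement"] in arrangements
            else parse_label(row["arrangement"])
        )
        cfg = readthrough_config(a, chain=params.chain_readthrough)
        if cfg not in code_cache:
            cI4 = truth_table_grid(cfg, Kv, muv, params)
            code_cache[cfg] = _pattern_codes(cI4, tau)
        try:
            target = _label_code(row["label"])
        except ValueError:
            continue  # AMBIGUOUS or unnamed: matches nothing
        agreement += code_cache[cfg] == target
    return GridResult(K, mu, agreement, n_observed=len(observed), tau=tau)


@dataclass
class ComparisonSummary:
    """Arrangement-level and orientation-pair-level concordance."""

    n: int
    n_agree: int
    n_disagree: int
    per_arrangement: pd.DataFrame = field(repr=False)
    pairs: pd.DataFrame = field(repr=False)

    def pair_counts(self) -> dict[str, int]:
        return self.pairs["status"].value_counts().to_dict()


def compare_predictions(
    predicted: pd.DataFrame, observed: pd.DataFrame
) -> ComparisonSummary:
    """Match predicted vs observed labels, tallied per arrangement and pair."""
    pred = predicted.set_index("arrangement")["label"]
    obs = observed.set_index("arrangement")["label"]
    missing = sorted(set(obs.index) - set(pred.index))
    if missing:
        raise KeyError(f"predictions missing for arrangements: {missing}")
    per = pd.DataFrame(
        {
            "arrangement": obs.index,
            "predicted": pred.loc[obs.index].to_numpy(),
            "observed": obs.to_numpy(),
        }
    )
    per["match"] = per["predicted"] == per["observed"]
    per["pair"] = [pair_id(parse_label(lbl)) for lbl in per["arrangement"]]

    pair_rows = []
    for pid, grp in per.groupby("pair", sort=True):
        if len(grp) == 2:
            n_ok = int(grp["match"].sum())
            status = {2: "both_agree", 1: "split", 0: "both_disagree"}[n_ok]
        else:
            status = "incomplete"
        pair_rows.append({"pair": pid, "status": status})
    pairs = pd.DataFrame(pair_rows, columns=["pair", "status"])
    n_agree = int(per["match"].sum())
    return ComparisonSummary(
        n=len(per),
        n_agree=n_agree,
        n_disagree=len(per) - n_agree,
        per_arrangement=per,
        pairs=pairs,
    )
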