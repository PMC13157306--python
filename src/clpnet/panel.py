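"""Two-wave panel container and its wide-CSV round trip.

Responses are stored as float arrays with NaN marking missing cells; observed
cells always hold valid integer codes for the item (0-3 ordinal, 0/1 binary).
Column convention for the wide format is ``<node_id>_t1`` / ``<node_id>_t2``
with an empty cell meaning missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .items import CANONICAL_ITEMS, ItemSpec

__all__ = ["PanelDataset", "read_panel_csv", "write_panel_csv"]


def _validate_codes(arr: np.ndarray, items: Sequence[ItemSpec], wave: str) -> None:
    for j, item in enumerate(items):
        col = arr[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        if not np.all(obs == np.round(obs)):
            raise ValueError(f"{item.node_id}_{wave}: non-integer codes present")
        if obs.min() < 0 or obs.max() > item.max_code:
            bad = obs[(obs < 0) | (obs > item.max_code)][0]
            raise ValueError(
                f"{item.node_id}_{wave}: code {bad:g} outside 0..{item.max_code}"
            )


@dataclass
class PanelDataset:
    """Participants x items x two waves, with missingness carried as NaN.

    Attributes
    ----------
    t1, t2 : (n, p) float arrays
        Integer item codes; NaN = missing.
    items : sequence of ItemSpec
        Node metadata in canonical order; defines p and the column order.
    covariates : DataFrame or None
        Optional participant-level covariates (MAR drivers / adjustment
        variables); never network nodes.
    """

    t1: np.ndarray
    t2: np.ndarray
    items: Sequence[ItemSpec] = field(default=CANONICAL_ITEMS)
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=float)
        self.t2 = np.asarray(self.t2, dtype=float)
        p = len(self.items)
        if self.t1.ndim != 2 or self.t2.ndim != 2:
            raise ValueError("t1/t2 must be 2-D (participants x items)")
        if self.t1.shape != self.t2.shape or self.t1.shape[1] != p:
            raise ValueError(
                f"shape mismatch: t1 {self.t1.shape}, t2 {self.t2.shape}, p={p}"
            )
        ids = [it.node_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node_ids in item list")
        _validate_codes(self.t1, self.items, "t1")
        _validate_codes(self.t2, self.items, "t2")
        if self.covariates is not None and len(self.covariates) != self.t1.shape[0]:
            raise ValueError("covariates row count differs from response matrices")

    # ---- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.t1.shape[0]

    @property
    def p(self) -> int:
        return self.t1.shape[1]

    @property
    def node_ids(self) -> list[str]:
        return [it.node_id for it in self.items]

    @property
    def missing_mask(self) -> np.ndarray:
        """(n, p, 2) boolean mask, True where a cell is missing."""
        return np.stack([np.isnan(self.t1), np.isnan(self.t2)], axis=2)

    def is_complete(self) -> bool:
        return not (np.isnan(self.t1).any() or np.isnan(self.t2).any())

    # ---- manipulation ---------------------------------------------------
    def take(self, indices: np.ndarray) -> "PanelDataset":
        """Row subset / resample (used by the bootstrap machinery)."""
        idx = np.asarray(indices)
        cov = None if self.covariates is None else self.covariates.iloc[idx].reset_index(drop=True)
        return PanelDataset(self.t1[idx], self.t2[idx], self.items, cov)

    def copy(self) -> "PanelDataset":
        cov = None if self.covariates is None else self.covariates.copy()
        return PanelDataset(self.t1.copy(), self.t2.copy(), self.items, cov)

    def with_responses(self, t1: np.ndarray, t2: np.ndarray) -> "PanelDataset":
        return replace(self, t1=t1, t2=t2)

    def oriented_waves(self, reverse_score: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Response matrices on the analysis scale.

        With ``reverse_score`` (default) positively worded CES-D items are
        flipped (v -> 3 - v) so that every depressive node points in the
        "more symptoms" direction before standardization.
        """
        t1, t2 = self.t1.copy(), self.t2.copy()
        if reverse_score:
            for j, item in enumerate(self.items):
                if item.reverse_scored:
                    t1[:, j] = item.max_code - t1[:, j]
                    t2[:, j] = item.max_code - t2[:, j]
        return t1, t2

    # ---- wide-format round trip ----------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for wave, arr in (("t1", self.t1), ("t2", self.t2)):
            for j, item in enumerate(self.items):
                cols[f"{item.node_id}_{wave}"] = arr[:, j]
        df = pd.DataFrame(cols)
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        items: Sequence[ItemSpec] = CANONICAL_ITEMS,
        covariate_columns: Sequence[str] | None = None,
    ) -> "PanelDataset":
        missing_cols = [
            f"{it.node_id}_{w}"
            for it in items
            for w in ("t1", "t2")
            if f"{it.node_id}_{w}" not in df.columns
        ]
        if missing_cols:
            raise ValueError(f"missing required columns: {missing_cols}")
        t1 = df[[f"{it.node_id}_t1" for it in items]].to_numpy(dtype=float)
        t2 = df[[f"{it.node_id}_t2" for it in items]].to_numpy(dtype=float)
        cov = None
        if covariate_columns:
            cov = df[list(covariate_columns)].reset_index(drop=True)
        return cls(t1, t2, items, cov)


def write_panel_csv(data: PanelDataset, path: str | Path) -> None:
    """Write the wide CSV (empty cell = missing, integer codes otherwise)."""
    df = data.to_dataframe()
    # keep integer appearance for observed codes
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{int(v)}" if float(v).is_integer() else f"{v}")
    out.to_csv(path, index=False)


def read_panel_csv(
    path: str | Path,
    items: Sequence[ItemSpec] = CANONICAL_ITEMS,
    covariate_columns: Sequence[str] | None = None,
) -> PanelDataset:
    """Read and range-validate a wide two-wave CSV.

    Raises a clear error for an empty file, an absent required column, or an
    out-of-range code (the PanelDataset constructor names the column).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: file is empty") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if covariate_columns is None:
        item_cols = {f"{it.node_id}_{w}" for it in items for w in ("t1", "t2")}
        covariate_columns = [c for c in df.columns if c not in item_cols] or None
    return PanelDataset.from_dataframe(df, items, covariate_columns)
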