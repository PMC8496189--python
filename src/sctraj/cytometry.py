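"""Index-sort fluorescence normalization, FACS trace-back, S-phase gating."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ID_COLUMNS = ("event_id", "plate_id", "well", "sequenced", "cell_type")


def channel_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def normalize_index_sort(table: pd.DataFrame, channels: list[str] | None = None) -> pd.DataFrame:
    """Scale each (plate, channel) to the unit interval.

    ``v' = clip((v - q01) / (q99 - q01), 0, 1)`` using the plate's 1st/99th
    percentiles, which absorbs per-session voltage offsets while resisting
    single-event outliers. A constant channel maps to 0 with a warning.
    """
    channels = channels or channel_columns(table)
    missing_any = [c for c in channels if c not in table.columns]
    if missing_any:
        raise ValueError(f"channels missing from table: {missing_any}")
    out = table.copy()
    for plate, idx in table.groupby("plate_id").groups.items():
        for ch in channels:
            vals = table.loc[idx, ch].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing channel values for plate {plate!r}, channel {ch!r}")
            q01, q99 = np.percentile(vals, [1, 99])
            if q99 - q01 <= 0:
                warnings.warn(
                    f"constant channel {ch!r} on plate {plate!r}; normalized to 0", stacklevel=2
                )
                out.loc[idx, ch] = 0.0
            else:
                out.loc[idx, ch] = np.clip((vals - q01) / (q99 - q01), 0.0, 1.0)
    return out


def facs_traceback(
    events: pd.DataFrame,
    sequenced_cells: pd.DataFrame,
    cluster_labels: dict,
) -> tuple[pd.DataFrame, list[str]]:
    """Join transcriptomic labels onto the cytometry events.

    ``sequenced_cells`` needs cell_id, plate_id and well columns;
    ``cluster_labels`` maps cell_id to a label. Every analyzed event is
    retained; events matching a sequenced (plate, well) receive that cell's
    label. Sequenced cells with no matching event are returned in the
    unmatched report rather than dropped silently. Duplicate (plate, well)
    events make the join ambiguous and raise.
    """
    key = list(zip(events["plate_id"], events["well"]))
    seqd = events["sequenced"] if "sequenced" in events else pd.Series(True, index=events.index)
    dup_keys = pd.Series([k for k, s in zip(key, seqd) if s and k[0] and k[1]])
    dup = dup_keys[dup_keys.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate (plate, well) events: {sorted(set(dup))[:3]}")

    lookup = {k: i for i, k in enumerate(key) if k[0] and k[1]}
    out = events.copy()
    out["label"] = ""
    unmatched = []
    for _, row in sequenced_cells.iterrows():
        k = (row["plate_id"], row["well"])
        if k in lookup:
            out.iloc[lookup[k], out.columns.get_loc("label")] = cluster_labels.get(
                row["cell_id"], ""
            )
        else:
            unmatched.append(row["cell_id"])
    return out, unmatched


@dataclass
class ProliferationResult:
    group: str
    threshold: float
    fraction_s_phase: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_s_phase <= 1.0:
            raise ValueError("fraction_s_phase must lie in [0, 1]")


def estimate_s_phase_fraction(
    hoechst_values: np.ndarray,
    mode_factor: float = 1.5,
    group: str = "",
) -> ProliferationResult:
    """Share of events above ``mode_factor`` times the primary DNA-content mode.

    The 2n (G0/G1) mode is located by a Gaussian kernel density estimate;
    events above ``mode_factor * mode`` are called S/G2-M. Scale-free: the
    KDE bandwidth scales with the data, so multiplying all values by a
    positive constant leaves the fraction unchanged.
    """
    v = np.asarray(hoechst_values, dtype=float)
    if len(v) < 100:
        raise ValueError("need at least 100 events")
    kde = stats.gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), 1024)
    dens = kde(grid)
    # local maxima; primary mode = highest density
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.nonzero(interior)[0] + 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    best = peaks[np.argmax(dens[peaks])]
    close = peaks[(dens[peaks] >= 0.95 * dens[best]) & (peaks != best)]
    if close.size:
        warnings.warn("ambiguous primary mode (two modes within 5% density); using the larger", stacklevel=2)
    mode = grid[best]
    threshold = mode_factor * mode
    frac = float((v > threshold).mean())
    return ProliferationResult(group=group, threshold=float(threshold), fraction_s_phase=frac)
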