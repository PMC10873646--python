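"""Object-based two-channel colocalization.

The quantity of interest is directional: the percentage of
reference-channel condensates that contain a punctum of another component
(number colocalized / number of reference condensates). The default rule
declares a reference object colocalized when its centroid falls inside an
object of the other channel — robust to size mismatch when one channel's
puncta are a superset of the other's; a mask-overlap rule (>= 50% of the
reference area by default) is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sparkquant.detection import CondensateSet

log = logging.getLogger(__name__)


@dataclass
class ColocResult:
    """Per-cell colocalization counts plus pooled summaries (percent)."""

    per_cell: pd.DataFrame  # cell_id, n_ref, n_coloc, fraction_pct
    pooled_fraction_pct: float  # sum(n_coloc) / sum(n_ref) * 100
    mean_fraction_pct: float  # mean of per-cell fractions
    sd_fraction_pct: float


def _match_one(ref: CondensateSet, other: CondensateSet, rule: str,
               min_overlap: float) -> tuple[int, int]:
    n_ref = len(ref)
    if n_ref == 0:
        raise ValueError("empty reference condensate set")
    if len(other) == 0:
        return n_ref, 0
    n_coloc = 0
    if rule == "centroid":
        axes = [c for c in ("centroid_z_um", "centroid_y_um", "centroid_x_um")
                if c in ref.props.columns]
        spacing = np.asarray(ref.spacing)
        for _, row in ref.props.iterrows():
            idx = tuple(int(round(row[a] / s)) for a, s in zip(axes, spacing))
            idx = tuple(np.clip(i, 0, n - 1) for i, n in zip(idx, other.labels.shape))
            if other.labels[idx] > 0:
                n_coloc += 1
    elif rule == "overlap":
        for lab in ref.props["label"]:
            m = ref.labels == lab
            if (other.mask & m).sum() >= min_overlap * m.sum():
                n_coloc += 1
    else:
        raise ValueError(f"unknown colocalization rule {rule!r}")
    return n_ref, n_coloc


def match_puncta(pairs, rule: str = "centroid", min_overlap: float = 0.5) -> ColocResult:
    """Colocalization fractions over cells.

    ``pairs`` is a list of (reference CondensateSet, other CondensateSet)
    from registered fields, one per cell (a single tuple is accepted).
    Cells whose reference set is empty are excluded with a log entry.
    """
    if rule not in ("centroid", "overlap"):
        raise ValueError(f"unknown colocalization rule {rule!r}")
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], CondensateSet):
        pairs = [pairs]
    rows = []
    for i, (ref, other) in enumerate(pairs):
        try:
            n_ref, n_coloc = _match_one(ref, other, rule, min_overlap)
        except ValueError as exc:
            log.warning("excluding cell %d from colocalization: %s", i, exc)
            continue
        rows.append(dict(cell_id=i, n_ref=n_ref, n_coloc=n_coloc,
                         fraction_pct=100.0 * n_coloc / n_ref))
    if not rows:
        raise ValueError("no cells with a non-empty reference set")
    per_cell = pd.DataFrame(rows)
    pooled = 100.0 * per_cell["n_coloc"].sum() / per_cell["n_ref"].sum()
    fr = per_cell["fraction_pct"]
    sd = float(fr.std(ddof=1)) if len(fr) > 1 else 0.0
    return ColocResult(per_cell=per_cell, pooled_fraction_pct=float(pooled),
                       mean_fraction_pct=float(fr.mean()), sd_fraction_pct=sd)


def coloc_panel(ref_sets, panel: dict, rule: str = "centroid",
                min_overlap: float = 0.5) -> pd.DataFrame:
    """Colocalization of one reference channel against a panel of others.

    ``panel`` maps component name -> list of CondensateSets (same cell
    order as ``ref_sets``). Returns one row per component with pooled and
    per-cell-averaged fractions.
    """
    rows = []
    for name, others in panel.items():
        if len(others) != len(ref_sets):
            raise ValueError(f"panel {name!r} has {len(others)} cells, expected {len(ref_sets)}")
        res = match_puncta(list(zip(ref_sets, others)), rule=rule, min_overlap=min_overlap)
        rows.append(dict(component=name, pooled_fraction_pct=res.pooled_fraction_pct,
                         mean_fraction_pct=res.mean_fraction_pct,
                         sd_fraction_pct=res.sd_fraction_pct,
                         n_cells=len(res.per_cell)))
    return pd.DataFrame(rows)
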