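"""Synapse-table reduction: glomerulus assignment, partner allocation, thresholds.

Works on a long-format synapse table (one row per synapse) with columns
``pre_id, pre_type, post_id, x, y, z`` and optionally ``post_class``
(uPN/mPN/LN/other).  The allocation procedure mirrors the connectome
analysis of olfactory-receptor-neuron output within one glomerulus:

1. drop pre→post connections carried by fewer than 3 synapses from a single
   ORN;
2. sum surviving synapses per postsynaptic neuron;
3. drop postsynaptic neurons with fewer than 10 total synapses;
4. normalize to the total for the ORN type;
5. rank partners by descending synapse count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClusteringError, InvalidArgumentError

__all__ = [
    "SYNAPSE_COLUMNS",
    "PartnerAllocation",
    "assign_glomerulus",
    "allocate_partners",
    "estimate_report_threshold",
    "class_composition",
    "innervation_symmetry",
]

SYNAPSE_COLUMNS = ("pre_id", "pre_type", "post_id", "x", "y", "z")


def _validate_table(table: pd.DataFrame, need_coords: bool = True) -> None:
    needed = SYNAPSE_COLUMNS if need_coords else SYNAPSE_COLUMNS[:3]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"synapse table missing columns {missing}")
    if need_coords and len(table):
        coords = table[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise InvalidArgumentError("synapse coordinates must be finite")


def assign_glomerulus(
    table: pd.DataFrame,
    n_clusters: int,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """Label every synapse with a glomerulus by k-means on its 3D coordinates.

    Returns a copy of the table with an integer ``glomerulus`` column.
    Labels are arbitrary but deterministic for a given seed, and stable under
    rigid motions of the coordinate frame up to relabeling.
    """
    from sklearn.cluster import KMeans

    _validate_table(table)
    if n_clusters < 1:
        raise InvalidArgumentError("n_clusters must be >= 1")
    out = table.copy()
    if n_clusters == 1:
        out["glomerulus"] = 0
        return out
    coords = table[["x", "y", "z"]].to_numpy(float)
    n_distinct = np.unique(coords, axis=0).shape[0]
    if n_distinct < n_clusters:
        raise ClusteringError(
            f"only {n_distinct} distinct coordinates for {n_clusters} clusters"
        )
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    out["glomerulus"] = km.fit_predict(coords)
    return out


@dataclass(frozen=True)
class PartnerAllocation:
    """Allocation of one ORN type's output synapses onto postsynaptic partners.

    ``partners`` has one row per retained partner with columns
    (post_id, total_synapses, fraction, rank), ranked 1..n by descending
    synapse count (ties broken by post_id).  ``dropped`` lists partners
    removed by the per-partner total filter with their pre-filter totals.
    """

    partners: pd.DataFrame
    dropped: pd.DataFrame
    min_per_connection: int
    min_total: int

    def __len__(self) -> int:
        return len(self.partners)

    @property
    def totals(self) -> pd.Series:
        return self.partners.set_index("post_id")["total_synapses"]


_EMPTY_PARTNERS = pd.DataFrame(
    {"post_id": pd.Series(dtype=object), "total_synapses": pd.Series(dtype=int),
     "fraction": pd.Series(dtype=float), "rank": pd.Series(dtype=int)}
)
_EMPTY_DROPPED = pd.DataFrame(
    {"post_id": pd.Series(dtype=object), "total_synapses": pd.Series(dtype=int)}
)


def allocate_partners(
    table: pd.DataFrame,
    min_per_connection: int = 3,
    min_total: int = 10,
    normalize_prefilter: bool = False,
) -> PartnerAllocation:
    """Filter, aggregate, normalize and rank a one-glomerulus synapse table.

    The table must already be restricted to a single glomerulus and ORN type.
    With ``normalize_prefilter`` fractions are taken over all synapses of the
    type before filtering instead of over the retained synapses (the default,
    under which retained fractions sum to 1).
    """
    _validate_table(table, need_coords=False)
    if min_per_connection < 0 or min_total < 0:
        raise InvalidArgumentError("filter thresholds must be non-negative")
    if table.empty:
        return PartnerAllocation(_EMPTY_PARTNERS.copy(), _EMPTY_DROPPED.copy(),
                                 min_per_connection, min_total)
    if table["pre_type"].nunique() > 1:
        raise InvalidArgumentError("table must contain a single pre_type (ORN type)")
    prefilter_total = len(table)

    per_conn = table.groupby(["pre_id", "post_id"]).size().rename("n")
    per_conn = per_conn[per_conn >= min_per_connection]
    if per_conn.empty:
        return PartnerAllocation(_EMPTY_PARTNERS.copy(), _EMPTY_DROPPED.copy(),
                                 min_per_connection, min_total)
    per_post = per_conn.groupby("post_id").sum()
    retained = per_post[per_post >= min_total]
    dropped = (per_post[per_post < min_total]
               .rename("total_synapses").reset_index().astype({"total_synapses": int}))
    if retained.empty:
        return PartnerAllocation(_EMPTY_PARTNERS.copy(), dropped,
                                 min_per_connection, min_total)
    denom = prefilter_total if normalize_prefilter else int(retained.sum())
    out = retained.rename("total_synapses").reset_index()
    out["fraction"] = out["total_synapses"] / denom
    out = out.sort_values(["total_synapses", "post_id"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["total_synapses"] = out["total_synapses"].astype(int)
    return PartnerAllocation(out, dropped, min_per_connection, min_total)


def estimate_report_threshold(allocation, observed_partner_count: int) -> int:
    """Smallest synapse count s with at most ``observed_partner_count`` partners above it.

    Used to estimate the reporting threshold of an anterograde labeling tool:
    given how many partners the tool reveals, find the minimal s such that
    #{partners with total > s} ≤ observed.  Accepts a
    :class:`PartnerAllocation` or any iterable of per-partner totals.
    """
    if observed_partner_count < 0:
        raise InvalidArgumentError("observed_partner_count must be >= 0")
    if isinstance(allocation, PartnerAllocation):
        totals = allocation.partners["total_synapses"].to_numpy(int)
    else:
        totals = np.asarray(list(allocation), int)
    if totals.size == 0:
        return 0
    totals = np.sort(totals)[::-1]
    if observed_partner_count >= totals.size:
        return 0
    # exactly `observed` partners exceed s once s reaches the (observed+1)-th total
    return int(totals[observed_partner_count])


def class_composition(
    allocation: PartnerAllocation, post_classes: pd.Series | dict | None = None
) -> pd.DataFrame:
    """Counts and percentages of retained partners per cell class.

    ``post_classes`` maps post_id to a class label (uPN/mPN/LN/...); missing
    or absent labels fall in "other".  Percentages sum to 100 over retained
    partners (they are lower bounds when annotations are incomplete).
    """
    df = allocation.partners
    if df.empty:
        return pd.DataFrame({"post_class": pd.Series(dtype=object),
                             "count": pd.Series(dtype=int),
                             "percent": pd.Series(dtype=float)})
    if post_classes is None:
        labels = pd.Series("other", index=df["post_id"])
    else:
        mapping = pd.Series(post_classes)
        labels = df["post_id"].map(mapping).fillna("other")
        labels.index = df["post_id"]
    counts = labels.groupby(labels).size().rename("count").reset_index()
    counts.columns = ["post_class", "count"]
    counts["percent"] = 100.0 * counts["count"] / counts["count"].sum()
    return counts.sort_values("count", ascending=False).reset_index(drop=True)


def innervation_symmetry(volume_left: float, volume_right: float) -> float:
    """Signed left/right innervation asymmetry, percent.

    100 * (L − R) / (2 * (L + R)): antisymmetric under swapping hemispheres
    and bounded in [−50, 50].
    """
    if volume_left < 0 or volume_right < 0:
        raise InvalidArgumentError("volumes must be non-negative")
    total = volume_left + volume_right
    if total == 0:
        raise InvalidArgumentError("symmetry undefined when both volumes are zero")
    return 100.0 * (volume_left - volume_right) / (2.0 * total)
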