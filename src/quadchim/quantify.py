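"""Chimera quantification: percentages, rescue sweep, type-IV estimator,
and library-type comparisons.

The central quantity is the percentage of retained reads falling into unused
inner-tag combinations, per multiplexed group (and per library "plate"),
stratified by chimera class and by the mismatch level allowed during barcode
rescue.

The type-IV extrapolation addresses the blind spot of equally sized groups:
intact molecules carrying a genuine fixed pair but the wrong outer index
(type IV) are only *visible* in groups that do not use every fixed pair. The
observed type-IV rate in those groups is scaled to the whole read set and
corrected by the ratio of all (group, pair) cases that could produce a
type-IV landing to the cases where one is identifiable:

    est_chimIV = (obs_chimIV / total_mg_reads) * total_reads
                 * (pos_chimIV / total_chimIV)

This is exact when every case is detectable and receives equal expected
landings, and an upper-bound-style extrapolation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scheme import ChimeraClass, ExperimentScheme, classify_combination


class QuantifyError(ValueError):
    """Undefined quantity (zero denominators, missing levels, ...)."""


CLASS_ORDER = [c.value for c in ChimeraClass]


def classify_counts(counts: pd.DataFrame, scheme: ExperimentScheme) -> pd.DataFrame:
    """Annotate a demultiplexing count table with chimera classes.

    ``counts`` needs columns group_id, i5, i7, mismatch_level, count; the
    result adds ``chimera_class`` and ``library_id``.
    """
    out = counts.copy()
    class_cache: dict[tuple[str, str, str], str] = {}
    lib_cache: dict[str, str] = {}

    def _cls(row) -> str:
        key = (row.group_id, row.i5, row.i7)
        if key not in class_cache:
            group = scheme.group(row.group_id)
            class_cache[key] = classify_combination(
                row.i5, row.i7, group, scheme
            ).value
        return class_cache[key]

    def _lib(gid: str) -> str:
        if gid not in lib_cache:
            lib_cache[gid] = scheme.library_of_group(gid).library_id
        return lib_cache[gid]

    out["chimera_class"] = [_cls(r) for r in out.itertuples()]
    out["library_id"] = [_lib(g) for g in out["group_id"]]
    return out


def summarize_chimeras(counts: pd.DataFrame, scheme: ExperimentScheme) -> pd.DataFrame:
    """Per (library, group, mismatch level, class): reads and percentages.

    ``pct_group`` is relative to the group's retained total, ``pct_library``
    to the library's; groups with zero retained reads report NaN percentages
    (undefined, not 0).
    """
    ann = classify_counts(counts, scheme)
    grouped = (
        ann.groupby(["library_id", "group_id", "mismatch_level", "chimera_class"],
                    observed=True)["count"]
        .sum()
        .reset_index(name="reads")
    )
    # Complete the class index so absent classes appear with 0 reads.
    keys = ann[["library_id", "group_id", "mismatch_level"]].drop_duplicates()
    full = keys.merge(
        pd.DataFrame({"chimera_class": CLASS_ORDER}), how="cross"
    ).merge(grouped, how="left").fillna({"reads": 0})
    full["reads"] = full["reads"].astype(int)
    group_tot = full.groupby(["group_id", "mismatch_level"])["reads"].transform("sum")
    lib_tot = full.groupby(["library_id", "mismatch_level"])["reads"].transform("sum")
    with np.errstate(invalid="ignore"):
        full["pct_group"] = np.where(
            group_tot > 0, 100.0 * full["reads"] / group_tot, np.nan
        )
        full["pct_library"] = np.where(
            lib_tot > 0, 100.0 * full["reads"] / lib_tot, np.nan
        )
    return full


def chimeric_percent_by_group(summary: pd.DataFrame) -> pd.DataFrame:
    """Total non-genuine percentage per (library, group, mismatch level)."""
    chim = summary[summary["chimera_class"] != ChimeraClass.GENUINE.value]
    return (
        chim.groupby(["library_id", "group_id", "mismatch_level"])["pct_group"]
        .sum(min_count=1)
        .reset_index(name="pct_chimeric")
    )


# ---------------------------------------------------------------------------
# Rescue sweep
# ---------------------------------------------------------------------------


@dataclass
class RescueSweep:
    """Cumulative and incremental retained/chimeric counts per rescue level."""

    table: pd.DataFrame  # k, retained, genuine, chimeric, new_* columns
    crossover_k: int | None  # smallest k >= 1 with new_chimeric > new_genuine

    def __iter__(self):  # pragma: no cover - convenience
        return iter((self.table, self.crossover_k))


def rescue_sweep(
    counts_by_level: dict[int, pd.DataFrame], scheme: ExperimentScheme
) -> RescueSweep:
    """Increments of genuine and chimeric retained reads between rescue levels.

    ``counts_by_level`` maps each mismatch level to the count table obtained
    by demultiplexing the *same* input at that level. Levels must be
    contiguous from the smallest; increments telescope back to the cumulative
    counts by construction.
    """
    levels = sorted(counts_by_level)
    if levels != list(range(levels[0], levels[0] + len(levels))):
        raise QuantifyError(f"mismatch levels not contiguous: {levels}")
    rows = []
    prev_gen = prev_chim = None
    crossover = None
    for k in levels:
        ann = classify_counts(counts_by_level[k], scheme)
        genuine = int(
            ann.loc[ann["chimera_class"] == ChimeraClass.GENUINE.value, "count"].sum()
        )
        chimeric = int(
            ann.loc[ann["chimera_class"] != ChimeraClass.GENUINE.value, "count"].sum()
        )
        new_gen = genuine - prev_gen if prev_gen is not None else genuine
        new_chim = chimeric - prev_chim if prev_chim is not None else chimeric
        rows.append(
            {
                "mismatch_level": k,
                "retained": genuine + chimeric,
                "genuine": genuine,
                "chimeric": chimeric,
                "new_genuine": new_gen,
                "new_chimeric": new_chim,
            }
        )
        if (
            crossover is None
            and prev_gen is not None
            and new_chim > new_gen
        ):
            crossover = k
        prev_gen, prev_chim = genuine, chimeric
    return RescueSweep(pd.DataFrame(rows), crossover)


# ---------------------------------------------------------------------------
# Type-IV estimator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TypeIVEstimate:
    """Inputs and result of the type-IV extrapolation."""

    obs_chimIV: int
    total_mg_reads: int
    total_reads: int
    pos_chimIV: int
    total_chimIV: int

    @property
    def est_chimIV(self) -> float:
        return estimate_type_iv(
            self.obs_chimIV,
            self.total_mg_reads,
            self.total_reads,
            self.pos_chimIV,
            self.total_chimIV,
        )


def estimate_type_iv(
    obs_chimIV: float,
    total_mg_reads: float,
    total_reads: float,
    pos_chimIV: float,
    total_chimIV: float,
) -> float:
    """est = (obs / total_mg_reads) * total_reads * (pos / total_chimIV)."""
    if total_mg_reads <= 0 or total_chimIV <= 0:
        raise QuantifyError(
            "type-IV estimate undefined: total_mg_reads and total_chimIV "
            "must be positive"
        )
    return (obs_chimIV / total_mg_reads) * total_reads * (pos_chimIV / total_chimIV)


def type_iv_inputs(
    counts: pd.DataFrame,
    scheme: ExperimentScheme,
    library_ids: list[str] | None = None,
) -> TypeIVEstimate:
    """Assemble estimator inputs from a (single-level) classified count table.

    ``library_ids`` restricts the computation (e.g. to one library type);
    case counts pos/total_chimIV are evaluated over the restricted scheme's
    groups but against the full scheme's pair usage.
    """
    if counts["mismatch_level"].nunique() > 1:
        raise QuantifyError("estimator expects counts from a single rescue level")
    ann = classify_counts(counts, scheme)
    if library_ids is not None:
        ann = ann[ann["library_id"].isin(library_ids)]
    groups = [
        g for g in scheme.groups()
        if library_ids is None or g.library_id in library_ids
    ]
    all_groups = scheme.groups()
    obs = int(ann.loc[ann["chimera_class"] == ChimeraClass.TYPE_IV.value, "count"].sum())
    iv_groups = set(
        ann.loc[
            (ann["chimera_class"] == ChimeraClass.TYPE_IV.value) & (ann["count"] > 0),
            "group_id",
        ]
    )
    total_mg = int(ann.loc[ann["group_id"].isin(iv_groups), "count"].sum())
    total = int(ann["count"].sum())
    pos = tot_id = 0
    for g in groups:
        for p in scheme.global_pairs:
            used_elsewhere = any(
                p.labels in other.pair_labels
                for other in all_groups
                if other.group_id != g.group_id
            )
            if not used_elsewhere:
                continue
            pos += 1
            if (
                classify_combination(p.i5.label, p.i7.label, g, scheme)
                is ChimeraClass.TYPE_IV
            ):
                tot_id += 1
    return TypeIVEstimate(obs, total_mg, total, pos, tot_id)


# ---------------------------------------------------------------------------
# Library-type comparisons
# ---------------------------------------------------------------------------


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise QuantifyError("need >= 2 observations per sample")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise QuantifyError("need >= 2 groups with >= 2 observations each")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def dunn_test(
    values: np.ndarray, labels: np.ndarray, p_adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's post-hoc rank test for all label pairs after Kruskal-Wallis.

    z_{ij} = (R̄_i - R̄_j) / sqrt(S * (1/n_i + 1/n_j)) with
    S = (N(N+1)/12) - (Σ(t³-t)) / (12(N-1)) correcting for rank ties.
    ``p_adjust``: "holm" (default) or "none".
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise QuantifyError("need >= 2 labels")
    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum()) / (12.0 * (N - 1))
    S = N * (N + 1) / 12.0 - tie_term
    mean_rank = {u: ranks[labels == u].mean() for u in uniq}
    n = {u: int((labels == u).sum()) for u in uniq}
    rows = []
    for i, j in itertools.combinations(uniq, 2):
        se = np.sqrt(S * (1.0 / n[i] + 1.0 / n[j]))
        z = (mean_rank[i] - mean_rank[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_1": i, "group_2": j, "z": z, "p_value": p})
    out = pd.DataFrame(rows)
    if p_adjust == "holm":
        out["p_adjusted"] = _holm(out["p_value"].tolist())
    elif p_adjust == "none":
        out["p_adjusted"] = out["p_value"]
    else:
        raise QuantifyError(f"unknown p_adjust {p_adjust!r}")
    return out


def compare_library_types(
    percentages: pd.DataFrame,
    value_col: str = "pct_chimeric",
    type_col: str = "library_type",
    library_col: str = "library_id",
) -> dict:
    """Standard comparisons on per-group chimera percentages.

    Returns a dict with the A-vs-B Mann-Whitney test, the across-library
    Kruskal-Wallis test, and Dunn's post-hoc table (Holm-adjusted).
    """
    types = list(pd.unique(percentages[type_col]))
    if len(types) != 2:
        raise QuantifyError("expected exactly two library types")
    a = percentages.loc[percentages[type_col] == types[0], value_col].to_numpy()
    b = percentages.loc[percentages[type_col] == types[1], value_col].to_numpy()
    u, p_u = mann_whitney(a, b)
    libs = [
        percentages.loc[percentages[library_col] == lib, value_col].to_numpy()
        for lib in pd.unique(percentages[library_col])
    ]
    h, p_h = kruskal_wallis(libs)
    dunn = dunn_test(
        percentages[value_col].to_numpy(), percentages[library_col].to_numpy()
    )
    return {
        "mann_whitney": {"types": types, "U": u, "p_value": p_u},
        "kruskal_wallis": {"H": h, "p_value": p_h},
        "dunn": dunn,
    }
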