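"""Community summaries: class composition, alpha diversity, rarefaction,
group tests, per-genus NB box statistics and top-N abundance matrices."""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .taxonomy import TaxonomyCall, percent


@dataclass
class ClassCompositionRow:
    sample: str
    class_counts: dict[str, int]
    algal_total: int
    nonalgal_total: int
    percentages: dict[str, float] = field(default_factory=dict)


@dataclass
class GenusNBSummary:
    genus: str
    n_otus: int
    median: float
    q1: float | None
    q3: float | None
    whisker_low: float | None
    whisker_high: float | None
    outliers: list[float] = field(default_factory=list)
    has_mixed: bool = False


def class_composition(
    calls: Mapping[str, TaxonomyCall],
    otu_table: pd.DataFrame,
) -> list[ClassCompositionRow]:
    """Distinct-OTU counts per class per sample, plus a pooled row.

    Percentages are computed on the algal (target-class) total of the
    row.  Non-target OTUs count into ``nonalgal_total`` only.
    """
    samples = list(otu_table.columns)
    rows: list[ClassCompositionRow] = []
    pooled_presence = otu_table.sum(axis=1)
    for sample in samples + ["pooled"]:
        presence = pooled_presence if sample == "pooled" else otu_table[sample]
        present = presence[presence > 0].index
        class_counts: dict[str, int] = {}
        nonalgal = 0
        for otu_id in present:
            call = calls.get(otu_id)
            if call is None or not call.is_target or call.lineage_class is None:
                nonalgal += 1
                continue
            class_counts[call.lineage_class] = class_counts.get(call.lineage_class, 0) + 1
        algal_total = sum(class_counts.values())
        percentages = {
            cls: percent(n, algal_total) for cls, n in sorted(class_counts.items())
        }
        rows.append(
            ClassCompositionRow(
                sample=sample,
                class_counts=dict(sorted(class_counts.items())),
                algal_total=algal_total,
                nonalgal_total=nonalgal,
                percentages=percentages,
            )
        )
    return rows


def mixed_otu_summary(
    otus: Sequence, calls: Mapping[str, TaxonomyCall]
) -> dict[str, float]:
    """Count and percentage of algal OTUs that carry clone-library members."""
    algal = [o for o in otus if (c := calls.get(o.id)) is not None and c.is_target]
    n_mixed = sum(1 for o in algal if o.has_clone_member)
    return {
        "n_algal": len(algal),
        "n_mixed": n_mixed,
        "mixed_pct": percent(n_mixed, len(algal)),
    }


def alpha_diversity(counts: Sequence[float] | np.ndarray) -> dict[str, float]:
    """Observed richness, Shannon H (natural log) and inverse Simpson."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        return {"observed": np.nan, "shannon": np.nan, "invsimpson": np.nan}
    p = arr[arr > 0] / total
    return {
        "observed": float((arr > 0).sum()),
        "shannon": float(-(p * np.log(p)).sum()),
        "invsimpson": float(1.0 / (p**2).sum()),
    }


def alpha_diversity_table(otu_table: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {s: alpha_diversity(otu_table[s].to_numpy()) for s in otu_table.columns}
    ).T


def rarefaction_curve(
    counts: Sequence[int] | np.ndarray,
    depths: Sequence[int],
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (and sd of) observed richness in subsamples without replacement."""
    arr = np.asarray(counts, dtype=np.int64)
    arr = arr[arr > 0]
    total = int(arr.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds sample total {total}")
        if depth == total:
            observed = np.full(n_reps, len(arr), dtype=float)
        else:
            observed = np.empty(n_reps)
            for r in range(n_reps):
                sub = rng.multivariate_hypergeometric(arr, depth)
                observed[r] = (sub > 0).sum()
        rows.append(
            {"depth": depth, "mean_observed": observed.mean(), "sd": observed.std(ddof=0)}
        )
    return pd.DataFrame(rows)


def rarefaction_expectation(counts: Sequence[int], depth: int) -> float:
    """Closed-form expected richness: sum(1 - C(N-n_i, d)/C(N, d))."""
    arr = np.asarray(counts, dtype=np.int64)
    arr = arr[arr > 0]
    total = int(arr.sum())
    expectation = 0.0
    for n_i in arr:
        # hypergeom: P(zero draws of this OTU at depth d)
        p_zero = sps.hypergeom.pmf(0, total, n_i, depth)
        expectation += 1.0 - p_zero
    return float(expectation)


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Mid-rank Kruskal-Wallis H with tie correction and chi-square p."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(v) == 0 for v in values):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*values)
    return float(h), float(p)


def genus_nb_boxstats(
    calls: Sequence[TaxonomyCall],
    mixed_otus: set[str] | None = None,
) -> list[GenusNBSummary]:
    """Box-plot statistics of best-NB values per genus-level group.

    Quartiles use linear interpolation; whiskers extend to the most
    extreme values within 1.5 IQR of the quartiles; values beyond are
    outliers.  Calls without a genus-rank label group under their
    "unidentified <order>/<class>" label.
    """
    mixed_otus = mixed_otus or set()
    groups: dict[str, list[TaxonomyCall]] = {}
    for call in calls:
        if not call.is_target:
            continue
        if call.assigned_rank in ("genotype", "species", "genus"):
            key = call.label.removesuffix(" sp.") if call.assigned_rank == "genus" else call.label
            if call.assigned_rank in ("genotype", "species"):
                # group by the genus prefix of the support labels when present
                key = call.label.rsplit("_sp", 1)[0] if "_sp" in call.label else call.label
        else:
            key = call.label
        groups.setdefault(key, []).append(call)

    out: list[GenusNBSummary] = []
    for genus in sorted(groups):
        members = groups[genus]
        nbs = np.sort([c.best_nb for c in members])
        has_mixed = any(c.otu_id in mixed_otus for c in members)
        if len(nbs) == 1:
            out.append(
                GenusNBSummary(
                    genus=genus, n_otus=1, median=float(nbs[0]),
                    q1=None, q3=None, whisker_low=None, whisker_high=None,
                    has_mixed=has_mixed,
                )
            )
            continue
        # classic hand formula: linear interpolation at rank (n+1)p
        q1, med, q3 = np.percentile(nbs, [25, 50, 75], method="weibull")
        iqr = q3 - q1
        in_low = nbs[nbs >= q1 - 1.5 * iqr]
        in_high = nbs[nbs <= q3 + 1.5 * iqr]
        whisker_low = float(in_low.min()) if len(in_low) else None
        whisker_high = float(in_high.max()) if len(in_high) else None
        outliers = [
            float(x) for x in nbs if x < q1 - 1.5 * iqr or x > q3 + 1.5 * iqr
        ]
        out.append(
            GenusNBSummary(
                genus=genus, n_otus=len(nbs), median=float(med),
                q1=float(q1), q3=float(q3),
                whisker_low=whisker_low, whisker_high=whisker_high,
                outliers=outliers, has_mixed=has_mixed,
            )
        )
    return out


def top_n_matrix(
    otu_table: pd.DataFrame,
    calls: Mapping[str, TaxonomyCall],
    n: int = 20,
    per_class: bool = True,
    group_map: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Top-``n`` OTUs by total reads, per class (or one pooled matrix).

    Ties at rank ``n`` break by OTU id.  When ``group_map`` is given the
    result carries boolean annotation columns: present in every groupA
    sample, and present in every sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = otu_table.sum(axis=1)
    by_class: dict[str, list[str]] = {}
    for otu_id in otu_table.index:
        call = calls.get(otu_id)
        if call is None or not call.is_target:
            continue
        cls = call.lineage_class or "unassigned"
        by_class.setdefault(cls if per_class else "all", []).append(otu_id)

    out: dict[str, pd.DataFrame] = {}
    for cls, otu_ids in sorted(by_class.items()):
        ranked = sorted(otu_ids, key=lambda o: (-totals[o], o))[:n]
        matrix = otu_table.loc[ranked].copy()
        if group_map is not None:
            a_samples = [
                s for s in otu_table.columns
                if group_map.get(s, "").startswith("groupA")
            ]
            matrix["found_in_all_groupA_sites"] = [
                bool((otu_table.loc[o, a_samples] > 0).all()) for o in ranked
            ]
            matrix["found_everywhere"] = [
                bool((otu_table.loc[o] > 0).all()) for o in ranked
            ]
        out[cls] = matrix
    return out
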