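"""Downstream analyses of the nucleation-score map.

Region/class frequency tables, the deletion start-by-end matrix with its
hotspot detector, alternative aliphatic-core detection among bridging
deletions, truncation series, ROC/AUC against familial-disease labels,
weighted correlation against in-vitro kinetic rate constants, and a
growth-rate utility for plate-reader curves.

Degenerate variants (several deletion intervals yielding one peptide) are
counted once in library-level statistics but expanded to every contributing
interval for position-indexed matrices and marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .library import (
    MULTI_DELETION,
    SINGLE_DELETION,
    TRUNCATION,
    DesignedLibrary,
    DesignedVariant,
)
from .scoring import NS_NEG, NS_POS, WT_LIKE

#: residues treated as aliphatic for core analyses (glycine included: the
#: aggregation-prone regions of the peptide consist of aliphatics and G)
ALIPHATIC = frozenset("GAVLIM")


@dataclass(frozen=True)
class RegionScheme:
    """Named intervals over WT positions (defaults: the five amyloid-beta
    regions; APR = aggregation-prone region)."""

    regions: tuple[tuple[str, int, int], ...] = (
        ("1-11", 1, 11),
        ("12-16", 12, 16),
        ("APR1", 17, 21),
        ("22-28", 22, 28),
        ("APR2", 29, 42),
    )
    nterm_end: int = 28
    length: int = 42
    aliphatic: frozenset = ALIPHATIC

    def __post_init__(self) -> None:
        covered = []
        for _, lo, hi in self.regions:
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, self.length + 1)):
            raise ValueError("regions must partition 1..length")

    def region_of(self, pos: int) -> str:
        for name, lo, hi in self.regions:
            if lo <= pos <= hi:
                return name
        raise ValueError(f"position {pos} outside 1..{self.length}")

    def super_region(self, pos: int) -> str:
        return "nterm" if pos <= self.nterm_end else "cterm"

    @property
    def apr_names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.regions if n.startswith("APR"))


@dataclass
class RegionLabels:
    regions: tuple[str, ...]
    super_region: str
    apr_category: str


def _removed_positions(spec, L: int) -> tuple[int, ...]:
    if spec.mclass == SINGLE_DELETION:
        return (spec.params[0],)
    if spec.mclass == MULTI_DELETION:
        return tuple(range(spec.params[0], spec.params[1] + 1))
    if spec.mclass == TRUNCATION:
        a, b = spec.params
        return tuple(range(1, a + 1)) + tuple(range(L - b + 1, L + 1))
    return ()


def assign_region(variant: DesignedVariant, scheme: RegionScheme) -> RegionLabels:
    """Region labels for a variant.

    Point mutations (substitutions, insertions, single deletions) map to the
    region containing their display position; the insertion sitting exactly
    between the N- and C-terminal halves counts as N-terminal. Interval
    mutations map to the set of regions their removed residues intersect,
    plus an APR category (APR1 only / APR2 only / APR1+APR2 / no APR).
    """
    spec = variant.specs[0]
    L = scheme.length
    if spec.mclass in ("substitution", "insertion", SINGLE_DELETION):
        pos = spec.display_position(None)  # position stored in params
        if spec.mclass == "insertion" and pos == scheme.nterm_end + 1:
            # inserted residue occupies the first core position but the gap
            # lies between the halves: reported as N-terminal
            return RegionLabels(
                (scheme.region_of(min(pos, L)),), "nterm", _apr_category((), scheme)
            )
        pos_eff = min(pos, L)
        if not 1 <= pos_eff <= L:
            raise ValueError(f"position {pos} outside 1..{L}")
        return RegionLabels(
            (scheme.region_of(pos_eff),),
            scheme.super_region(pos_eff if spec.mclass != "insertion" else min(pos, L)),
            _apr_category((), scheme),
        )
    removed = _removed_positions(spec, L)
    regions = tuple(
        dict.fromkeys(scheme.region_of(p) for p in removed)
    )
    supers = {scheme.super_region(p) for p in removed}
    super_label = supers.pop() if len(supers) == 1 else "both"
    return RegionLabels(regions, super_label, _apr_category(regions, scheme))


def _apr_category(regions: tuple[str, ...], scheme: RegionScheme) -> str:
    aprs = [n for n in scheme.apr_names if n in regions]
    if not aprs:
        return "no APR"
    if len(aprs) == len(scheme.apr_names):
        return "+".join(scheme.apr_names)
    return f"{aprs[0]} only"


def class_frequency_table(
    scores: pd.DataFrame,
    library: DesignedLibrary,
    scheme: RegionScheme | None = None,
    fdr_levels: tuple[float, ...] = (0.1,),
    by: str = "super_region",
) -> pd.DataFrame:
    """Counts and fractions of NS+/NS-/WT-like per (class x region x FDR).

    ``scores`` must carry q and ns; classification is recomputed at each
    requested FDR level from the stored q-values, so one fit serves all
    levels. Grouping is by ``super_region`` (1-28 vs 29-42) or ``region``.
    """
    scheme = scheme or RegionScheme()
    rows = []
    idx = scores.index if scores.index.name == "variant_id" else scores.set_index("variant_id").index
    s = scores if scores.index.name == "variant_id" else scores.set_index("variant_id")
    for v in library:
        if v.is_wt or v.variant_id not in s.index:
            continue
        rec = s.loc[v.variant_id]
        labels = assign_region(v, scheme)
        group = labels.super_region if by == "super_region" else (
            labels.regions[0] if len(labels.regions) == 1 else labels.apr_category
        )
        for level in fdr_levels:
            if not np.isfinite(rec["q"]) or not np.isfinite(rec["ns"]):
                cls = rec["effect_class"]  # non_nucleating propagates
            elif rec["q"] < level and rec["ns"] > 0:
                cls = NS_POS
            elif rec["q"] < level and rec["ns"] < 0:
                cls = NS_NEG
            else:
                cls = WT_LIKE
            rows.append((v.assigned_class, group, level, cls))
    long = pd.DataFrame(rows, columns=["mclass", "region", "fdr", "effect_class"])
    table = (
        long.groupby(["mclass", "region", "fdr", "effect_class"])
        .size()
        .rename("count")
        .reset_index()
    )
    totals = table.groupby(["mclass", "region", "fdr"])["count"].transform("sum")
    table["fraction"] = table["count"] / totals
    return table


def deletion_effect_matrix(
    scores: pd.DataFrame,
    library: DesignedLibrary,
    include_singles: bool = True,
    include_truncations: bool = True,
) -> pd.DataFrame:
    """Long-format (first deleted, last deleted) -> NS matrix.

    Degenerate variants populate every contributing interval with their one
    shared score. Single deletions occupy the diagonal; pure one-sided
    truncations appear as end-touching intervals when included (a truncation
    removing residues from both ends has no contiguous interval and is
    skipped).
    """
    s = scores if scores.index.name == "variant_id" else scores.set_index("variant_id")
    L = len(library.wt)
    rows = []
    for v in library:
        if v.is_wt or v.variant_id not in s.index:
            continue
        rec = s.loc[v.variant_id]
        for spec in v.specs:
            if spec.mclass == SINGLE_DELETION and include_singles:
                cell = (spec.params[0], spec.params[0])
            elif spec.mclass == MULTI_DELETION:
                cell = (spec.params[0], spec.params[1])
            elif spec.mclass == TRUNCATION and include_truncations:
                a, b = spec.params
                if a and b:
                    continue
                cell = (1, a) if a else (L - b + 1, L)
            else:
                continue
            rows.append(
                (
                    v.variant_id,
                    cell[0],
                    cell[1],
                    rec["ns"],
                    rec["effect_class"],
                )
            )
    return pd.DataFrame(
        rows, columns=["variant_id", "first_del", "last_del", "ns", "effect_class"]
    )


def marginal_frequencies(
    matrix: pd.DataFrame,
    by: str = "first_del",
    positions: range | None = None,
    min_n: int = 1,
) -> pd.DataFrame:
    """Per-position NS+/NS-/WT-like frequencies along one matrix axis.

    ``by`` is 'first_del', 'last_del' or 'missing' (any interval covering the
    position). Each degenerate interval contributes separately, mirroring how
    the matrix is drawn. Positions backed by fewer than ``min_n`` intervals
    get NaN frequencies (a threshold-on-maximum rule is meaningless on
    one-variant cells).
    """
    rows = []
    if positions is None:
        positions = range(
            int(matrix["first_del"].min()), int(matrix["last_del"].max()) + 1
        )
    for pos in positions:
        if by == "first_del":
            sel = matrix[matrix["first_del"] == pos]
        elif by == "last_del":
            sel = matrix[matrix["last_del"] == pos]
        elif by == "missing":
            sel = matrix[(matrix["first_del"] <= pos) & (matrix["last_del"] >= pos)]
        else:
            raise ValueError(f"unknown axis {by!r}")
        n = len(sel)
        for cls in (NS_POS, NS_NEG, WT_LIKE):
            rows.append(
                (pos, cls, (sel["effect_class"] == cls).sum(), n)
            )
    out = pd.DataFrame(rows, columns=["position", "effect_class", "count", "n"])
    out["frequency"] = np.where(
        out["n"] >= max(1, min_n), out["count"] / out["n"].replace(0, 1), np.nan
    )
    return out


def detect_hotspot(frequencies: pd.Series) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions with frequency > max/2.

    ``frequencies`` is indexed by position. Returns all maximal runs; the
    longest (ties: all longest) is the hotspot. Scale-invariant. Empty when
    every frequency is zero or missing.
    """
    freq = frequencies.dropna()
    if freq.empty or (freq <= 0).all():
        return []
    half = freq.max() / 2.0
    hot = freq[freq > half].index.to_list()
    runs: list[tuple[int, int]] = []
    for pos in sorted(hot):
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    longest = max(e - s for s, e in runs)
    return [r for r in runs if r[1] - r[0] == longest]


def hotspot_analysis(
    scores: pd.DataFrame,
    library: DesignedLibrary,
    scheme: RegionScheme | None = None,
    min_n: int = 5,
) -> dict[str, list[tuple[int, int]]]:
    """Detect the deletion hotspot on both matrix axes.

    Marginal NS+ frequencies are taken over N-terminal internal deletions
    (intervals not touching either peptide end, last removed residue within
    1..nterm_end), per first and per last deleted position; the half-maximum
    run rule is applied to each axis. Returns {'first_del': runs,
    'last_del': runs}.
    """
    scheme = scheme or RegionScheme()
    matrix = deletion_effect_matrix(scores, library)
    sub = matrix[
        (matrix["first_del"] >= 2) & (matrix["last_del"] <= scheme.nterm_end)
    ]
    out = {}
    for axis in ("first_del", "last_del"):
        marg = marginal_frequencies(sub, by=axis, min_n=min_n)
        freq = marg[marg["effect_class"] == NS_POS].set_index("position")["frequency"]
        out[axis] = detect_hotspot(freq)
    return out


@dataclass
class CoreVariant:
    variant_id: str
    start: int
    end: int
    replacement: str
    core_length: int
    ns: float


def alternative_core_scan(
    library: DesignedLibrary,
    scores: pd.DataFrame,
    scheme: RegionScheme | None = None,
) -> pd.DataFrame:
    """Bridging deletions that rebuild the aliphatic core from upstream residues.

    Selects internal deletions [s, e] removing residues in both the 1-28 and
    29-42 halves; the replacement segment is the e-28 residues immediately
    preceding the junction (those now occupying former core positions) and
    the variant is kept iff that segment is exclusively aliphatic. The core
    length is the maximal contiguous aliphatic run ending at the variant's
    C-terminus. Degenerate products are evaluated once, on their lead interval.
    """
    scheme = scheme or RegionScheme()
    s = scores if scores.index.name == "variant_id" else scores.set_index("variant_id")
    wt = library.wt
    rows = []
    for v in library:
        if v.assigned_class != MULTI_DELETION:
            continue
        spec = v.specs[0]
        start, end = spec.params
        if not (start <= scheme.nterm_end and end > scheme.nterm_end):
            continue
        n_core_removed = end - scheme.nterm_end
        repl_start = start - n_core_removed
        if repl_start < 1:
            continue
        replacement = wt[repl_start - 1: start - 1]
        if not replacement or not set(replacement) <= scheme.aliphatic:
            continue
        ns = s.loc[v.variant_id, "ns"] if v.variant_id in s.index else np.nan
        rows.append(
            (
                v.variant_id,
                start,
                end,
                replacement,
                aliphatic_core_length(v.canonical_seq, scheme.aliphatic),
                ns,
            )
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "start", "end", "replacement", "core_length", "ns"]
    )


def aliphatic_core_length(seq: str, aliphatic: frozenset = ALIPHATIC) -> int:
    """Length of the maximal contiguous aliphatic run ending at the C-terminus."""
    n = 0
    for aa in reversed(seq):
        if aa in aliphatic:
            n += 1
        else:
            break
    return n


def truncation_series(
    scores: pd.DataFrame, library: DesignedLibrary, ci: float = 0.95
) -> pd.DataFrame:
    """Ordered profiles of pure N-terminal (b=0) and C-terminal (a=0) truncations.

    One row per truncation with the number of residues removed, the merged NS
    with a normal-approximation confidence interval, and the effect class.
    """
    from scipy import stats as _st

    zcrit = _st.norm.ppf(0.5 + ci / 2.0)
    s = scores if scores.index.name == "variant_id" else scores.set_index("variant_id")
    rows = []
    for v in library:
        if v.assigned_class != TRUNCATION:
            continue
        a, b = v.specs[0].params
        if a and b:
            continue
        side = "N" if a else "C"
        if v.variant_id in s.index:
            rec = s.loc[v.variant_id]
            ns, se, cls = rec["ns"], rec["se"], rec["effect_class"]
        else:
            ns = se = np.nan
            cls = "unscored"
        rows.append(
            (v.variant_id, side, a or b, ns, se,
             ns - zcrit * se, ns + zcrit * se, cls)
        )
    out = pd.DataFrame(
        rows,
        columns=["variant_id", "side", "n_removed", "ns", "se", "ci_lo", "ci_hi",
                 "effect_class"],
    )
    return out.sort_values(["side", "n_removed"]).reset_index(drop=True)


def roc_auc(ns_values, labels) -> float:
    """AUC: probability a random positive outranks a random negative (ties 1/2)."""
    ns_values = np.asarray(ns_values, float)
    labels = np.asarray(labels).astype(int)
    ok = np.isfinite(ns_values)
    ns_values, labels = ns_values[ok], labels[ok]
    if len(set(labels)) < 2:
        raise ValueError("ROC needs at least one positive and one negative label")
    return float(roc_auc_score(labels, ns_values))


def weighted_pearson(x, y, w=None) -> float:
    """Pearson correlation with weighted means and covariances.

    Uniform weights reduce to the ordinary Pearson coefficient; the default
    weighting for score-vs-kinetics comparisons is 1/SE^2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    if len(x) != len(y) or len(x) != len(w):
        raise ValueError("x, y, w must have equal length")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance")
    return float(cov / np.sqrt(vx * vy))


def kinetics_correlation(
    scores: pd.DataFrame, kinetics: pd.DataFrame, rate: str = "lambda"
) -> float:
    """Weighted Pearson R between NS and a log kinetic rate constant.

    ``kinetics`` columns: variant_id, lambda and/or kappa, optional weight
    (default 1/SE^2 from the score table).
    """
    s = scores if scores.index.name == "variant_id" else scores.set_index("variant_id")
    merged = kinetics.join(s[["ns", "se"]], on="variant_id", how="inner").dropna(
        subset=["ns", rate]
    )
    if (merged[rate] <= 0).any():
        raise ValueError("kinetic rate constants must be positive")
    w = (
        merged["weight"].to_numpy(float)
        if "weight" in merged
        else 1.0 / merged["se"].to_numpy(float) ** 2
    )
    return weighted_pearson(merged["ns"], np.log(merged[rate]), w)


def growth_rate(time, od, window: int = 10) -> float:
    """Maximum sliding-window slope of ln(OD) versus time.

    The exponential-phase growth rate: the largest least-squares slope of
    ln(OD) over ``window`` consecutive points.
    """
    time = np.asarray(time, float)
    od = np.asarray(od, float)
    if np.any(od <= 0):
        raise ValueError("OD values must be positive")
    if len(time) < window:
        raise ValueError(f"need at least {window} points")
    y = np.log(od)
    best = -np.inf
    for i in range(len(time) - window + 1):
        t = time[i: i + window]
        slope = np.polyfit(t, y[i: i + window], 1)[0]
        best = max(best, slope)
    return float(best)
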