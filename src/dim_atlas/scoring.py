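"""Nucleation-score estimation from selection counts.

The measurement model: for variant i in biological replicate r, the
enrichment score is the log ratio of output to input frequency,

    ES_ir = ln(c_out/T_out) - ln(c_in/T_in),

and the nucleation score is the enrichment relative to the wild type,
NS_ir = ES_ir - ES_WT,r. Replicate scores are combined by inverse-variance
weighting; per-replicate variances are the Poisson (delta-method) counting
term 1/c_in + 1/c_out + 1/wt_in + 1/wt_out, optionally augmented by a
replicate-scatter component estimated from the data. Variants are classified
against WT with a two-sided z-test and Benjamini-Hochberg FDR control.

The public surface follows the Model/Results convention: build a
:class:`NucleationModel` from a count table, call :meth:`~NucleationModel.fit`,
and read estimates, uncertainties and classes off the returned
:class:`NucleationResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NS_POS = "NS+"
NS_NEG = "NS-"
WT_LIKE = "WT-like"
NON_NUCLEATING = "non_nucleating"


def enrichment_score(count_in, count_out, total_in, total_out):
    """ES = ln(f_out) - ln(f_in); natural log. NaN when either count is zero."""
    count_in = np.asarray(count_in, float)
    count_out = np.asarray(count_out, float)
    if np.any(np.asarray(total_in) <= 0) or np.any(np.asarray(total_out) <= 0):
        raise ValueError("sample totals must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        es = np.log(count_out / total_out) - np.log(count_in / total_in)
    return np.where((count_in > 0) & (count_out > 0), es, np.nan)


def nucleation_score(es_i, es_wt):
    """NS = ES_i - ES_WT (NaN propagates)."""
    return np.asarray(es_i, float) - np.asarray(es_wt, float)


def error_estimate(count_in, count_out, wt_in, wt_out):
    """Delta-method counting standard deviation of NS in one replicate.

    sigma^2 = 1/c_in + 1/c_out + 1/wt_in + 1/wt_out, treating the four counts
    as independent Poisson draws (the multinomial totals are large).
    """
    arrs = [np.asarray(a, float) for a in (count_in, count_out, wt_in, wt_out)]
    with np.errstate(divide="ignore"):
        var = sum(np.where(a > 0, 1.0 / a, np.nan) for a in arrs)
    return np.sqrt(var)


def merge_replicates(ns_r, sigma_r):
    """Inverse-variance weighted mean and its standard error over replicates.

    Entries with non-finite NS or sigma are ignored; returns (nan, nan) when
    no replicate is usable.
    """
    ns_r = np.asarray(ns_r, float)
    sigma_r = np.asarray(sigma_r, float)
    ok = np.isfinite(ns_r) & np.isfinite(sigma_r) & (sigma_r > 0)
    if not ok.any():
        return math.nan, math.nan
    w = 1.0 / sigma_r[ok] ** 2
    return float(np.sum(w * ns_r[ok]) / w.sum()), float(1.0 / math.sqrt(w.sum()))


def classify_variants(
    ns, se, fdr: float = 0.1, method: str = "fdr_bh"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided z-test against zero with FDR control across all scored variants.

    Returns (z, p, q, class) arrays; variants with missing NS/SE stay
    unclassified (NaN statistics, WT-like label is NOT applied to them here).
    """
    ns = np.asarray(ns, float)
    se = np.asarray(se, float)
    z = np.full(ns.shape, np.nan)
    ok = np.isfinite(ns) & np.isfinite(se)
    bad = ok & (se == 0) & (ns != 0)
    if bad.any():
        raise FloatingPointError(
            f"{bad.sum()} variants have SE = 0 with nonzero NS (degenerate)"
        )
    ok &= se > 0
    z[ok] = ns[ok] / se[ok]
    p = np.full(ns.shape, np.nan)
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    q = np.full(ns.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method=method)[1]
    cls = np.full(ns.shape, WT_LIKE, dtype=object)
    cls[ok & (q < fdr) & (ns > 0)] = NS_POS
    cls[ok & (q < fdr) & (ns < 0)] = NS_NEG
    return z, p, q, cls


@dataclass
class NucleationResults:
    """Fit output: per-variant scores, uncertainties and effect classes.

    Attributes
    ----------
    scores : DataFrame indexed by variant_id with per-replicate ES/NS/sigma
        columns, merged ``ns``, ``se``, ``z``, ``p``, ``q`` and
        ``effect_class``.
    sigma_add : fitted additive replicate-variance component (0 when the
        error model is 'counts' or 'multiplicative').
    phi : fitted multiplicative inflation (1 unless model='multiplicative').
    """

    model: "NucleationModel"
    scores: pd.DataFrame
    sigma_add: float
    phi: float
    fdr: float
    fdr_method: str

    def class_counts(self) -> pd.Series:
        return self.scores["effect_class"].value_counts()

    def summary(self) -> str:
        s = self.scores
        scored = s["ns"].notna().sum()
        lines = [
            "Nucleation score fit",
            "=" * 44,
            f"variants in table            {len(s):>10d}",
            f"variants scored              {scored:>10d}",
            f"biological replicates        {self.model.n_bio:>10d}",
            f"error model                  {self.model.error_model:>10s}",
            f"additive rep. SD             {math.sqrt(self.sigma_add):>10.4f}",
            f"multiplicative inflation     {self.phi:>10.3f}",
            f"FDR level ({self.fdr_method})        {self.fdr:>10.2f}",
            "-" * 44,
        ]
        for name, count in self.class_counts().items():
            lines.append(f"{name:<28s} {count:>10d}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.scores.to_csv(path)


class NucleationModel:
    """Inverse-variance replicate model for selection-assay enrichment.

    Parameters
    ----------
    counts : long-format count table with columns variant_id, bio_rep,
        tech_rep (optional if already pooled), count_in, count_out.
    wt_id : identifier of the wild-type reference row.
    error_model : 'additive' (default) adds a between-replicate variance
        component (method of moments, clipped at zero) to the counting
        variance; 'multiplicative' inflates counting variances by a global
        factor >= 1; 'counts' uses the pure counting term.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        wt_id: str = "WT",
        pool_technical: bool = True,
        error_model: str = "additive",
    ) -> None:
        required = {"variant_id", "bio_rep", "count_in", "count_out"}
        missing = required - set(counts.columns)
        if missing:
            raise ValueError(f"count table is missing columns: {sorted(missing)}")
        if error_model not in ("additive", "multiplicative", "counts"):
            raise ValueError(f"unknown error model {error_model!r}")
        if pool_technical:
            counts = (
                counts.groupby(["variant_id", "bio_rep"], as_index=False)[
                    ["count_in", "count_out"]
                ].sum()
            )
        self.counts = counts
        self.wt_id = wt_id
        self.error_model = error_model
        self.bio_reps = sorted(counts["bio_rep"].unique())
        self.n_bio = len(self.bio_reps)
        if wt_id not in set(counts["variant_id"]):
            raise ValueError(f"WT reference {wt_id!r} absent from the count table")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NucleationModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, fdr: float = 0.1, fdr_method: str = "fdr_bh") -> NucleationResults:
        cin = self.counts.pivot(index="variant_id", columns="bio_rep", values="count_in")
        cout = self.counts.pivot(index="variant_id", columns="bio_rep", values="count_out")
        cin = cin.reindex(columns=self.bio_reps).fillna(0.0)
        cout = cout.reindex(columns=self.bio_reps).fillna(0.0)
        tin = cin.sum(axis=0).to_numpy(float)
        tout = cout.sum(axis=0).to_numpy(float)

        es = enrichment_score(cin.to_numpy(float), cout.to_numpy(float), tin, tout)
        iwt = cin.index.get_loc(self.wt_id)
        es_wt = es[iwt]
        if not np.all(np.isfinite(es_wt)):
            raise ValueError("WT has zero input or output counts in some replicate")
        ns_r = nucleation_score(es, es_wt)
        sigma_cnt = error_estimate(
            cin.to_numpy(float), cout.to_numpy(float),
            cin.to_numpy(float)[iwt], cout.to_numpy(float)[iwt],
        )
        sigma_cnt = np.where(np.isfinite(ns_r), sigma_cnt, np.nan)

        sigma_add2, phi = self._fit_dispersion(ns_r, sigma_cnt, iwt)
        sigma_r = np.sqrt(phi * sigma_cnt**2 + sigma_add2)

        merged = np.array([merge_replicates(n, s) for n, s in zip(ns_r, sigma_r)])
        ns, se = merged[:, 0], merged[:, 1]
        # exact WT centering (the weighted mean of identical zeros is zero,
        # but re-center so NS(WT) == 0 to machine precision regardless)
        ns = ns - ns[iwt]

        z, p, q, cls = classify_variants(ns, se, fdr=fdr, method=fdr_method)
        cls = cls.copy()
        # non-nucleating: input reads throughout, zero output everywhere
        dead = (cout.to_numpy(float).sum(axis=1) == 0) & (
            (cin.to_numpy(float) > 0).all(axis=1)
        )
        cls[dead] = NON_NUCLEATING
        cls[iwt] = WT_LIKE

        out = pd.DataFrame(index=cin.index)
        for j, r in enumerate(self.bio_reps):
            out[f"es_rep{r}"] = es[:, j]
            out[f"ns_rep{r}"] = ns_r[:, j]
            out[f"sigma_rep{r}"] = sigma_r[:, j]
        out["ns"] = ns
        out["se"] = se
        out["z"] = z
        out["p"] = p
        out["q"] = q
        out["effect_class"] = cls
        out.loc[dead, ["ns", "se", "z", "p", "q"]] = np.nan
        return NucleationResults(
            model=self,
            scores=out,
            sigma_add=float(sigma_add2),
            phi=float(phi),
            fdr=fdr,
            fdr_method=fdr_method,
        )

    def _fit_dispersion(self, ns_r, sigma_cnt, iwt) -> tuple[float, float]:
        """Method-of-moments replicate-scatter fit.

        Across replicates, Var(NS_ir) = counting variance + an extra term
        from biological noise (including the shared WT reference noise). The
        additive model estimates that term as the mean over variants of
        (empirical replicate variance - mean counting variance), clipped at
        zero (the sample variance is unbiased, so the mean of the differences
        is too); the multiplicative model estimates a global variance ratio.
        Only variants with every replicate finite (excluding WT, whose NS is
        identically zero) inform the fit.
        """
        if self.error_model == "counts" or self.n_bio < 2:
            return 0.0, 1.0
        full = np.isfinite(ns_r).all(axis=1) & np.isfinite(sigma_cnt).all(axis=1)
        full[iwt] = False
        if full.sum() < 10:
            return 0.0, 1.0
        s2 = np.var(ns_r[full], axis=1, ddof=1)
        v_cnt = np.mean(sigma_cnt[full] ** 2, axis=1)
        if self.error_model == "additive":
            return float(max(0.0, np.mean(s2 - v_cnt))), 1.0
        return 0.0, float(max(1.0, np.mean(s2) / np.mean(v_cnt)))
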