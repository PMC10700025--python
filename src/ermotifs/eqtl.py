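"""Two-condition nominal cis-eQTL scan and condition-specific classification.

For every variant within 1 Mb of a gene's TSS, expression is regressed on
genotype dosage (no covariates) separately under control and ER-stress (TM,
tunicamycin) conditions.  Nominal p-values come from the Pearson-correlation
t statistic; slopes and standard errors are recovered from (r, n, sd ratios)
the way they are conventionally extracted from FastQTL-style output.
Benjamini-Hochberg FDR flags significant associations (default
p_adj < 0.001); pairs are then classified as shared or condition-specific,
and condition effect sizes are compared with a Welch two-sample construction
on the slope summaries, calling a difference at 90% confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ASSOC_COLUMNS = [
    "variant_id", "gene_id", "condition", "n",
    "slope", "se", "r", "p_nominal",
]


@dataclass
class GenotypeMatrix:
    """Variant-by-sample dosage matrix (0/1/2; NaN = missing call)."""

    dosages: pd.DataFrame  # index: variant_id, columns: sample ids
    meta: pd.DataFrame     # index: variant_id; chrom, pos, ref, alt

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def allele_frequency(self) -> pd.Series:
        return self.dosages.mean(axis=1, skipna=True) / 2.0

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, meta = [], []
        for var in vcf:
            gts = np.array([a[0] + a[1] if a[0] >= 0 and a[1] >= 0 else np.nan
                            for a in ((g[0], g[1]) for g in var.genotypes)])
            vid = var.ID or f"{var.CHROM}_{var.POS}_{var.REF}_{var.ALT[0]}"
            rows.append(pd.Series(gts, index=samples, name=vid))
            meta.append(
                {"variant_id": vid, "chrom": var.CHROM, "pos": var.POS,
                 "ref": var.REF, "alt": var.ALT[0]}
            )
        dosages = pd.DataFrame(rows)
        meta_df = pd.DataFrame(meta).set_index("variant_id")
        return cls(dosages, meta_df)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2-intensity matrix for one condition."""

    values: pd.DataFrame   # index: gene_id, columns: sample ids
    condition: str         # "control" or "tm"
    genes: pd.DataFrame    # index: gene_id; chrom, tss, strand

    @classmethod
    def from_tsv(
        cls, expr_path: str | Path, genes_path: str | Path, condition: str
    ) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        genes = pd.read_csv(genes_path, sep="\t", dtype={"chrom": str})
        if "tss" not in genes.columns:
            genes["tss"] = np.where(
                genes["strand"] == "+", genes["start"] + 1, genes["end"]
            )
        return cls(values, condition, genes.set_index("gene_id"))


def cis_pairs(
    genes: pd.DataFrame,
    variants: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Candidate (gene, variant) pairs with |pos - TSS| <= window, same chrom.

    ``genes`` needs gene_id/chrom/tss columns (or index = gene_id);
    ``variants`` needs variant_id/chrom/pos (or index = variant_id).  The
    window bound is closed: a variant exactly ``window`` away is tested.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    g = genes.reset_index() if "gene_id" not in genes.columns else genes
    v = variants.reset_index() if "variant_id" not in variants.columns else variants
    out = []
    for chrom, gc in g.groupby("chrom", sort=False):
        vc = v[v["chrom"] == chrom]
        if vc.empty:
            continue
        pos = vc["pos"].to_numpy(np.int64)
        order = np.argsort(pos, kind="stable")
        pos_s = pos[order]
        vid_s = vc["variant_id"].to_numpy(object)[order]
        for row in gc.itertuples(index=False):
            lo = np.searchsorted(pos_s, row.tss - window, side="left")
            hi = np.searchsorted(pos_s, row.tss + window, side="right")
            if hi > lo:
                out.append(
                    pd.DataFrame(
                        {"gene_id": row.gene_id, "variant_id": vid_s[lo:hi],
                         "distance": np.abs(pos_s[lo:hi] - row.tss)}
                    )
                )
    if not out:
        return pd.DataFrame(columns=["gene_id", "variant_id", "distance"])
    return pd.concat(out, ignore_index=True)


def nominal_scan(
    pairs: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
) -> pd.DataFrame:
    """Nominal linear regression for each candidate pair, one condition.

    Per pair over complete-case samples: Pearson r between dosage and
    expression; t = r*sqrt((n-2)/(1-r^2)); two-sided t tail with n-2 df;
    slope = r*sd(expr)/sd(dosage); se = |slope|/|t|.  Pairs with < 3
    complete samples, zero dosage variance or zero expression variance are
    skipped with a reason code; perfect fits (|r| = 1) are kept with se = 0
    and flagged so downstream effect-size tests can exclude them.
    """
    shared = [s for s in genotypes.dosages.columns if s in expression.values.columns]
    D = genotypes.dosages[shared].to_numpy(float)
    E = expression.values[shared].to_numpy(float)
    vindex = {v: i for i, v in enumerate(genotypes.dosages.index)}
    gindex = {g: i for i, g in enumerate(expression.values.index)}
    rows, skipped = [], []
    for gene_id, variant_id in zip(pairs["gene_id"], pairs["variant_id"]):
        gi = gindex.get(gene_id)
        vi = vindex.get(variant_id)
        if gi is None or vi is None:
            skipped.append((variant_id, gene_id, "missing_feature"))
            continue
        d, e = D[vi], E[gi]
        ok = ~(np.isnan(d) | np.isnan(e))
        n = int(ok.sum())
        if n < 3:
            skipped.append((variant_id, gene_id, "too_few_samples"))
            continue
        d, e = d[ok], e[ok]
        sd_d, sd_e = d.std(ddof=1), e.std(ddof=1)
        if sd_d == 0:
            skipped.append((variant_id, gene_id, "constant_genotype"))
            continue
        if sd_e == 0:
            skipped.append((variant_id, gene_id, "constant_expression"))
            continue
        r = float(np.corrcoef(d, e)[0, 1])
        r = max(-1.0, min(1.0, r))
        slope = r * sd_e / sd_d
        if abs(r) >= 1.0 - 1e-15:
            rows.append(
                {"variant_id": variant_id, "gene_id": gene_id,
                 "condition": expression.condition, "n": n, "slope": slope,
                 "se": 0.0, "r": r, "p_nominal": 0.0, "perfect_fit": True}
            )
            continue
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        se = abs(slope) / abs(t) if t != 0 else np.nan
        rows.append(
            {"variant_id": variant_id, "gene_id": gene_id,
             "condition": expression.condition, "n": n, "slope": slope,
             "se": se, "r": r, "p_nominal": p, "perfect_fit": False}
        )
    assoc = pd.DataFrame(rows, columns=ASSOC_COLUMNS + ["perfect_fit"])
    assoc.attrs["skipped"] = pd.DataFrame(
        skipped, columns=["variant_id", "gene_id", "reason"]
    )
    return assoc


def fdr_adjust(assoc: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Benjamini-Hochberg step-up over all tested pairs in one condition.

    Adds ``p_adj`` and ``significant`` (p_adj < alpha) columns.
    """
    out = assoc.copy()
    if len(out) == 0:
        out["p_adj"] = []
        out["significant"] = []
        return out
    pvals = out["p_nominal"].to_numpy(float)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out["p_adj"] = np.maximum(p_adj, pvals)  # BH never below nominal
    out["significant"] = out["p_adj"] < alpha
    return out


def classify_conditions(
    assoc_control: pd.DataFrame,
    assoc_tm: pd.DataFrame,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Label each variant-gene pair shared / control_only / tm_only / neither.

    Both scans must cover the identical pair universe; a mismatch raises an
    error listing the missing pairs.  Pairs significant in both conditions
    are shared; in exactly one, condition-specific.
    """
    key = ["variant_id", "gene_id"]
    a = assoc_control.set_index(key)
    b = assoc_tm.set_index(key)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            "association universes differ; missing pairs: "
            f"{list(only_a[:5])} / {list(only_b[:5])}"
        )
    sig_a = a["p_adj"] < alpha if "p_adj" in a else fdr_adjust(assoc_control, alpha).set_index(key)["significant"]
    sig_b = b["p_adj"] < alpha if "p_adj" in b else fdr_adjust(assoc_tm, alpha).set_index(key)["significant"]
    sig_a, sig_b = sig_a.sort_index(), sig_b.sort_index()
    cls = np.select(
        [sig_a & sig_b, sig_a & ~sig_b, ~sig_a & sig_b],
        ["shared", "control_only", "tm_only"],
        default="neither",
    )
    out = pd.DataFrame(index=sig_a.index).reset_index()
    out["class"] = cls
    return out


def condition_gene_sets(classification: pd.DataFrame) -> dict[str, set[str]]:
    """Gene-level sets per class (shared / control_only / tm_only)."""
    return {
        c: set(classification.loc[classification["class"] == c, "gene_id"])
        for c in ("shared", "control_only", "tm_only")
    }


def effect_size_difference(
    slope_a: float, se_a: float, n_a: int,
    slope_b: float, se_b: float, n_b: int,
    confidence: float = 0.90,
) -> dict:
    """Welch comparison of two condition slopes from summary statistics.

    d = slope_a - slope_b; se_d = sqrt(se_a^2 + se_b^2); degrees of freedom
    by Welch-Satterthwaite on (se^2, n-2) per condition; the difference is
    significant when the confidence interval excludes 0.  Degenerate SEs
    (perfect fits) are flagged and not tested.  Normal quantile used when
    df > 200 (difference < 1e-3).
    """
    if se_a == 0 or se_b == 0 or np.isnan(se_a) or np.isnan(se_b):
        return {"difference": slope_a - slope_b, "ci": (np.nan, np.nan),
                "significant": False, "df": np.nan, "degenerate": True}
    d = slope_a - slope_b
    va, vb = se_a ** 2, se_b ** 2
    se_d = np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 2) + vb ** 2 / (n_b - 2))
    q = 0.5 + confidence / 2.0
    tcrit = stats.norm.ppf(q) if df > 200 else stats.t.ppf(q, df)
    ci = (d - tcrit * se_d, d + tcrit * se_d)
    return {"difference": d, "ci": ci, "significant": not (ci[0] <= 0.0 <= ci[1]),
            "df": float(df), "degenerate": False}


def effect_size_table(
    assoc_a: pd.DataFrame,
    assoc_b: pd.DataFrame,
    confidence: float = 0.90,
) -> pd.DataFrame:
    """Vectorised Welch effect-size comparison for matched associations.

    Frames are aligned on (variant_id, gene_id); rows present in only one
    frame are dropped.  Returns difference, CI bounds and the significance
    flag per pair.
    """
    key = ["variant_id", "gene_id"]
    merged = assoc_a.merge(assoc_b, on=key, suffixes=("_a", "_b"))
    va = merged["se_a"].to_numpy(float) ** 2
    vb = merged["se_b"].to_numpy(float) ** 2
    degenerate = (va == 0) | (vb == 0) | np.isnan(va) | np.isnan(vb)
    d = merged["slope_a"].to_numpy(float) - merged["slope_b"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_d = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (
            va ** 2 / (merged["n_a"].to_numpy(float) - 2)
            + vb ** 2 / (merged["n_b"].to_numpy(float) - 2)
        )
    q = 0.5 + confidence / 2.0
    tcrit = np.where(df > 200, stats.norm.ppf(q), stats.t.ppf(q, np.where(df > 0, df, 1)))
    lo, hi = d - tcrit * se_d, d + tcrit * se_d
    significant = ~((lo <= 0) & (0 <= hi)) & ~degenerate
    return pd.DataFrame(
        {"variant_id": merged["variant_id"], "gene_id": merged["gene_id"],
         "difference": d, "ci_low": lo, "ci_high": hi, "df": df,
         "significant": significant, "degenerate": degenerate}
    )


def genotype_summaries(
    variant_id: str,
    gene_id: str,
    genotypes: GenotypeMatrix,
    expr_control: ExpressionMatrix,
    expr_tm: ExpressionMatrix,
) -> pd.DataFrame:
    """Per-genotype-class expression means and TM/control fold changes.

    For each dosage class (0/1/2) with >= 1 sample, reports the mean log2
    intensity under each condition and fold change 2^(mean_tm -
    mean_control).  Empty classes are omitted.
    """
    d = genotypes.dosages.loc[variant_id]
    rows = []
    for dosage in (0.0, 1.0, 2.0):
        samples = d.index[d == dosage]
        sc = [s for s in samples if s in expr_control.values.columns]
        st = [s for s in samples if s in expr_tm.values.columns]
        if not sc and not st:
            continue
        mean_c = float(expr_control.values.loc[gene_id, sc].mean()) if sc else np.nan
        mean_t = float(expr_tm.values.loc[gene_id, st].mean()) if st else np.nan
        rows.append(
            {"variant_id": variant_id, "gene_id": gene_id, "dosage": int(dosage),
             "n_control": len(sc), "n_tm": len(st),
             "mean_control": mean_c, "mean_tm": mean_t,
             "fold_change": float(2.0 ** (mean_t - mean_c))
             if sc and st else np.nan}
        )
    return pd.DataFrame(rows)
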