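"""SNP quality control, predicted gene expression, and ancestry PCs.

Predicted tissue-specific expression is the PrediXcan application step: a
weighted sum of effect-allele dosages under a pre-trained eQTL weight set.
QC follows standard GWAS practice: per-SNP call rate, Hardy-Weinberg exact
test, and folded minor allele frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeMatrix:
    """Subjects-by-SNPs dosage matrix with allele metadata.

    ``dosages`` is a DataFrame indexed by subject id with one column per SNP
    id, values in [0, 2] (count of the alt allele) or NaN for missing.
    ``snps`` is indexed by SNP id with columns ``ref`` and ``alt``.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.columns.duplicated().any():
            raise ValueError("duplicated SNP ids in dosage matrix")
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def subjects(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    def subset(self, snp_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[list(snp_ids)], self.snps.loc[list(snp_ids)])


def snp_call_rate(column) -> float:
    """Fraction of subjects with a non-missing dosage for one SNP."""
    col = np.asarray(column, dtype=float)
    if col.size == 0:
        raise ValueError("call rate undefined for an empty column")
    return float(np.mean(~np.isnan(col)))


def minor_allele_frequency(column) -> float:
    """Folded minor allele frequency, mean(dosage)/2 folded to <= 0.5."""
    col = np.asarray(column, dtype=float)
    good = col[~np.isnan(col)]
    if good.size == 0:
        raise ValueError("MAF undefined: all dosages missing")
    p = float(np.mean(good)) / 2.0
    return min(p, 1.0 - p)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts (the standard SNP-HWE construction) and sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("HWE test needs at least one genotype")
    rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele count
    # log-probability of each feasible heterozygote count, same parity as rare
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    lg = math.lgamma

    def logprob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            lg(n + 1) - lg(h + 1) - lg(hom_rare + 1) - lg(hom_common + 1)
            + h * math.log(2)
            + lg(rare + 1) + lg(2 * n - rare + 1) - lg(2 * n + 1)
        )

    logp = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square goodness-of-fit test against HWE proportions."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("HWE test needs at least one genotype")
    p = (2 * n_AA + n_Aa) / (2 * n)
    exp = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(exp == 0):
        return 1.0  # monomorphic: no departure measurable
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, exact_max_n: int = 1000) -> float:
    """HWE p-value: exact enumeration, chi-square above ``exact_max_n`` subjects."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n <= exact_max_n:
        return hwe_exact_test(n_AA, n_Aa, n_aa)
    return hwe_chi2_test(n_AA, n_Aa, n_aa)


def hwe_test_dosages(column) -> float:
    """HWE p-value from dosages, assigning classes by nearest-integer rounding.

    Fractional imputed dosages are rounded rather than re-tested; this is a
    documented limitation of dosage-level QC.
    """
    col = np.asarray(column, dtype=float)
    good = col[~np.isnan(col)]
    if good.size == 0:
        raise ValueError("HWE undefined: all dosages missing")
    g = np.clip(np.rint(good), 0, 2).astype(int)
    return hwe_test(int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2)))


def snp_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, folded MAF and HWE p-value."""
    rows = []
    for snp in gm.snp_ids:
        col = gm.dosages[snp].to_numpy(dtype=float)
        cr = snp_call_rate(col)
        if cr == 0.0:
            rows.append((snp, 0.0, np.nan, np.nan))
            continue
        rows.append((snp, cr, minor_allele_frequency(col), hwe_test_dosages(col)))
    return pd.DataFrame(rows, columns=["snp", "call_rate", "maf", "hwe_p"]).set_index(
        "snp"
    )


def qc_filter(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_hwe_p: float = 0.001,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs failing call-rate, HWE or MAF thresholds.

    Returns the filtered matrix and a per-SNP report (snp, call_rate, maf,
    hwe_p, status, reason); ``reason`` concatenates every violated rule.
    """
    if len(gm.snp_ids) == 0:
        empty = pd.DataFrame(
            columns=["call_rate", "maf", "hwe_p", "status", "reason"],
            index=pd.Index([], name="snp"),
        )
        return gm, empty
    report = snp_stats(gm)
    reasons = []
    for snp, row in report.iterrows():
        why = []
        if row["call_rate"] < min_call_rate:
            why.append("low_call_rate")
        if not np.isnan(row["hwe_p"]) and row["hwe_p"] < min_hwe_p:
            why.append("hwe_deviation")
        if np.isnan(row["maf"]) or row["maf"] < min_maf:
            why.append("low_maf")
        reasons.append(";".join(why))
    report["status"] = ["fail" if r else "pass" for r in reasons]
    report["reason"] = reasons
    keep = report.index[report["status"] == "pass"]
    return gm.subset(keep), report


def predict_expression(
    gm: GenotypeMatrix, weights: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Predicted expression per subject and gene: sum of weight x dosage.

    ``weights`` columns: gene, rsid, ref_allele, eff_allele, weight.  When a
    weight's effect allele is the matrix's ref allele the dosage is flipped
    to ``2 - d``; SNPs absent from the matrix (or with mismatched alleles)
    are skipped and counted.  Missing dosages are imputed to the SNP's mean
    observed dosage (twice the effect-allele frequency).
    """
    required = {"gene", "rsid", "ref_allele", "eff_allele", "weight"}
    if not required.issubset(weights.columns):
        raise ValueError(f"weight table must have columns {sorted(required)}")
    values = pd.DataFrame(index=gm.subjects)
    info: dict = {"skipped": {}, "flipped": {}, "used": {}}
    for gene, wtab in weights.groupby("gene", sort=False):
        if wtab["rsid"].duplicated().any():
            raise ValueError(f"duplicated SNP id in weights for gene {gene}")
        total = np.zeros(len(gm.subjects))
        used = flipped = 0
        skipped = []
        for _, w in wtab.iterrows():
            rsid = w["rsid"]
            if rsid not in gm.snp_ids:
                skipped.append(rsid)
                continue
            d = gm.dosages[rsid].to_numpy(dtype=float)
            ref, alt = gm.snps.loc[rsid, "ref"], gm.snps.loc[rsid, "alt"]
            if w["eff_allele"] == alt:
                pass
            elif w["eff_allele"] == ref:
                d = 2.0 - d
                flipped += 1
            else:
                skipped.append(rsid)  # allele mismatch, cannot orient
                continue
            if np.all(np.isnan(d)):
                skipped.append(rsid)
                continue
            d = np.where(np.isnan(d), np.nanmean(d), d)
            total += float(w["weight"]) * d
            used += 1
        if used == 0:
            raise ValueError(
                f"no weight SNPs for gene {gene!r} overlap the genotype matrix"
            )
        values[gene] = total
        info["skipped"][gene] = skipped
        info["flipped"][gene] = flipped
        info["used"][gene] = used
    return values, info


def ancestry_pcs(gm: GenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """Top-k principal components of column-standardized dosages.

    Missing dosages are mean-imputed per SNP; zero-variance SNPs are
    dropped.  Scores have unit variance; the sign convention makes the
    largest-magnitude SNP loading of each component positive.
    """
    if k == 0:
        return pd.DataFrame(index=gm.subjects)
    n = len(gm.subjects)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} subjects for {k} PCs")
    X = gm.dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    sd = X.std(axis=0, ddof=1)
    variable = sd > 0
    if not variable.any():
        raise ValueError("cannot compute PCs of a constant genotype matrix")
    Z = (X[:, variable] - X[:, variable].mean(axis=0)) / sd[variable]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(k, len(S))
    scores = U[:, :k] * S[:k]
    for j in range(k):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    scores = scores / scores.std(axis=0, ddof=1)
    return pd.DataFrame(
        scores, index=gm.subjects, columns=[f"pc{j + 1}" for j in range(k)]
    )
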