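"""SES composite construction: PCA of the indicator battery with diagnostics.

Five socioeconomic indicators (household income, maternal education, public
assistance, food security, perceived resource availability) are standardized
and reduced to their first principal component; the composite is the
loading-weighted sum of z-scores, oriented so higher = higher SES.  KMO and
Bartlett sphericity diagnose whether the battery supports a single factor.
Promax rotation of a single retained component is the identity, so no
rotation engine is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PCAResult:
    loadings: pd.Series  # first-component structure loadings, one per indicator
    eigenvalues: np.ndarray
    variance_explained: float  # leading eigenvalue / p
    kmo: float
    bartlett_stat: float
    bartlett_p: float
    n: int


def standardize_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """z-score every column (sample SD, n-1); a constant column is an error."""
    sds = table.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant indicator column(s): {constant}")
    return (table - table.mean()) / sds


def kmo_index(corr: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling adequacy of a correlation matrix.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, where q
    are the anti-image partial correlations from the (pseudo-)inverse.
    """
    R = np.asarray(corr, dtype=float)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    if r2 < 1e-12:
        raise ValueError("KMO undefined (no correlations)")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient correlation matrix; using pseudo-inverse for KMO")
        Rinv = np.linalg.pinv(R)
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(corr: np.ndarray, n: int) -> tuple[float, float]:
    """Bartlett's test that the correlation matrix is the identity.

    statistic = -(n - 1 - (2p + 5)/6) * ln|R|, chi-square with p(p-1)/2 df.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError(f"Bartlett test needs n > p (got n={n}, p={p})")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("singular correlation matrix: Bartlett statistic undefined")
    statistic = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(statistic), float(stats.chi2.sf(statistic, df))


def pca_first_component(standardized: pd.DataFrame) -> PCAResult:
    """First principal component of the indicator correlation matrix.

    Loadings are eigenvector * sqrt(eigenvalue); the sign convention makes
    the majority of loadings positive.  Promax rotation with one retained
    component is the identity and is therefore not applied.
    """
    n, p = standardized.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 subjects")
    R = np.corrcoef(standardized.to_numpy(dtype=float), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    v1 = eigvecs[:, 0]
    if np.sum(v1 > 0) < np.sum(v1 < 0):
        v1 = -v1
    loadings = pd.Series(v1 * np.sqrt(max(eigvals[0], 0.0)), index=standardized.columns)
    kmo = kmo_index(R)
    try:
        bart_stat, bart_p = bartlett_sphericity(R, n)
    except ValueError:
        warnings.warn("singular correlation matrix; Bartlett statistic undefined")
        bart_stat, bart_p = float("nan"), float("nan")
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigvals,
        variance_explained=float(eigvals[0] / p),
        kmo=kmo,
        bartlett_stat=bart_stat,
        bartlett_p=bart_p,
        n=n,
    )


def composite_score(
    standardized: pd.DataFrame, loadings: pd.Series, orient_on: str | None = "income"
) -> pd.Series:
    """Loading-weighted sum of z-scored indicators, oriented higher = higher SES.

    If the loading of ``orient_on`` (default the income column, falling back
    to the first column) is negative, the whole composite is sign-flipped.
    """
    if set(loadings.index) != set(standardized.columns):
        raise ValueError(
            "loadings and indicator columns do not match: "
            f"{sorted(loadings.index)} vs {sorted(standardized.columns)}"
        )
    loadings = loadings.reindex(standardized.columns)
    anchor = orient_on if orient_on in standardized.columns else standardized.columns[0]
    sign = -1.0 if loadings[anchor] < 0 else 1.0
    values = standardized.to_numpy(dtype=float) @ (sign * loadings.to_numpy())
    return pd.Series(values, index=standardized.index, name="ses_composite")


def median_split(composite: pd.Series) -> pd.Series:
    """Split at the median; ties at the median go to the lower group."""
    if len(composite) < 2:
        raise ValueError("median split needs at least 2 subjects")
    med = composite.median()
    labels = pd.Series(
        np.where(composite <= med, "lower", "higher"),
        index=composite.index,
        name="ses_group",
    )
    if (labels == "lower").all():
        warnings.warn("degenerate median split: all values <= median")
    return labels


def diagnostics_table(
    table: pd.DataFrame, result: PCAResult, types: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-indicator summary (type, mean, SD, loading) for reporting."""
    types = types or {}
    return pd.DataFrame(
        {
            "type": [types.get(c, "") for c in table.columns],
            "mean": table.mean().round(4),
            "sd": table.std(ddof=1).round(4),
            "loading": result.loadings.round(4),
        }
    )
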