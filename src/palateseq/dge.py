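"""Transcript-density differential gene expression.

The statistic pipeline, per gene, on ROI transcript densities:

* LG2FC computed on the **raw** mean densities, with a symmetric
  pseudocount to keep zero-expression ratios finite
  (``log2((mean_a + eps) / (mean_b + eps))``);
* p-values from a variance-gated two-sample t-test on **log2(x + 1)**
  transformed densities: a two-tailed F test of the variance ratio decides
  between Student's (equal-variance, pooled) and Welch's (unequal-variance)
  t-test;
* Benjamini–Hochberg step-up adjustment across all genes tested;
* volcano classification: a gene is up (down) when its chosen p-value is
  below ``p_threshold`` and its LG2FC exceeds ``lfc_threshold`` in absolute
  value.

A generic one-sided hypergeometric over-representation test against
user-supplied gene sets rounds out the stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DGEConfig",
    "TTestResult",
    "log2_fold_change",
    "log2p1_transform",
    "variance_gated_t_test",
    "benjamini_hochberg",
    "classify_deg",
    "run_dge",
    "volcano_table",
    "volcano_plot",
    "over_representation",
    "read_gene_sets",
]

UP, DOWN, NS = "up", "down", "ns"

DGE_CSV_COLUMNS = [
    "gene", "mean_a", "mean_b", "lfc", "variance_p", "branch", "t",
    "p_raw", "p_adj", "class",
]


@dataclass(frozen=True)
class DGEConfig:
    """Thresholds of the density DGE stage.

    ``pseudocount`` is in density units; the default, 1/6400 µm⁻², is one
    transcript per default-size ROI.  ``use_adjusted_p_for_class`` selects
    whether volcano classification thresholds the BH-adjusted (default) or
    the raw p-value; the choice is stamped into outputs.
    """

    f_alpha: float = 0.05
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    pseudocount: float = 1.0 / 6400.0
    use_adjusted_p_for_class: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.f_alpha < 1):
            raise ValueError("f_alpha must be in (0, 1)")
        if self.p_threshold <= 0 or self.lfc_threshold <= 0 or self.pseudocount < 0:
            raise ValueError("thresholds must be positive and pseudocount >= 0")


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 1.0 / 6400.0) -> float:
    """log2 fold change of raw mean densities, group A over group B.

    Returns ``log2((mean_a + eps)/(mean_b + eps))`` with ``eps`` the
    pseudocount applied symmetrically to both terms.

    Raises
    ------
    ValueError
        For negative means, or a zero denominator (or numerator) when the
        pseudocount is 0 — set a pseudocount to handle zero-expression genes.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("mean densities must be >= 0")
    if pseudocount == 0 and (mean_a == 0 or mean_b == 0):
        raise ValueError(
            "zero mean density with pseudocount 0; set a pseudocount "
            "(e.g. one transcript per ROI area) to compute a finite LG2FC"
        )
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


def log2p1_transform(values) -> np.ndarray:
    """Elementwise log2(x + 1), the variance-reducing normalization applied
    before testing.  Monotone; maps 0 to 0.  Rejects negative input."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log2(x + 1) requires non-negative input")
    return np.log2(arr + 1.0)


class TTestResult(NamedTuple):
    variance_p: float
    branch: str  # "student" | "welch"
    t: float
    p: float
    degenerate: bool = False


def variance_gated_t_test(a, b, f_alpha: float = 0.05) -> TTestResult:
    """Two-sample t-test with an F-test variance gate.

    The variance ratio F (larger sample variance in the numerator) is tested
    two-tailed; when its p-value falls below ``f_alpha`` the groups are
    treated as heteroscedastic and Welch's t-test (Welch–Satterthwaite
    degrees of freedom) is used, otherwise Student's pooled-variance t-test.
    Both t-tests are two-tailed.

    When both samples have zero variance the comparison is degenerate: the
    result carries ``p = 1`` and ``degenerate=True`` by convention.

    Raises
    ------
    ValueError
        If either sample has fewer than two observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        return TTestResult(variance_p=1.0, branch="student", t=0.0, p=1.0, degenerate=True)
    if va >= vb:
        num, dfn, den, dfd = va, na - 1, vb, nb - 1
    else:
        num, dfn, den, dfd = vb, nb - 1, va, na - 1
    fstat = num / den if den > 0 else np.inf
    variance_p = float(min(1.0, 2.0 * stats.f.sf(fstat, dfn, dfd)))
    if variance_p < f_alpha:
        branch = "welch"
        t, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        branch = "student"
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(variance_p=variance_p, branch=branch, t=float(t), p=float(p))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    On the sorted p-values, ``p_adj(i) = min_{j >= i} (m/j) p(j)`` capped at
    1, returned in the input order.  Monotone nondecreasing along the sorted
    order and idempotent.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def classify_deg(lfc: float, p: float, config: DGEConfig | None = None) -> str:
    """Volcano classification: "up" / "down" / "ns".

    Up when ``p < p_threshold`` and ``lfc > lfc_threshold``; down when
    ``p < p_threshold`` and ``lfc < -lfc_threshold``; otherwise not
    significant.
    """
    config = config or DGEConfig()
    if not (np.isfinite(lfc) and np.isfinite(p)):
        raise ValueError("lfc and p must be finite")
    if p < config.p_threshold:
        if lfc > config.lfc_threshold:
            return UP
        if lfc < -config.lfc_threshold:
            return DOWN
    return NS


def run_dge(matrix_a, matrix_b, config: DGEConfig | None = None) -> pd.DataFrame:
    """Full density DGE between two ROI sets sharing a gene index.

    Per gene: LG2FC on raw mean densities (group A over group B), a
    variance-gated t-test on log2(x+1)-transformed densities, BH adjustment
    across all genes, and volcano classification.  Genes with zero variance
    in both groups are flagged ``degenerate`` (p = 1) and never classified
    up or down.

    Returns a table with columns ``gene, mean_a, mean_b, lfc, variance_p,
    branch, t, p_raw, p_adj, class, degenerate``; its ``attrs`` record the
    config, including which p-value the classification used.

    Raises
    ------
    ValueError
        On a gene-index mismatch (message lists the symmetric difference) or
        fewer than two ROIs in either matrix.
    """
    config = config or DGEConfig()
    genes_a, genes_b = set(matrix_a.gene_index), set(matrix_b.gene_index)
    if genes_a != genes_b:
        diff = sorted(genes_a.symmetric_difference(genes_b))
        raise ValueError(f"gene indices differ; symmetric difference: {diff}")
    if len(matrix_a.counts) < 2 or len(matrix_b.counts) < 2:
        raise ValueError("each group needs at least 2 ROIs")
    genes = matrix_a.gene_index
    dens_a = matrix_a.densities
    dens_b = matrix_b.densities[genes]
    rows = []
    for gene in genes:
        xa = dens_a[gene].to_numpy(float)
        xb = dens_b[gene].to_numpy(float)
        res = variance_gated_t_test(log2p1_transform(xa), log2p1_transform(xb),
                                    f_alpha=config.f_alpha)
        rows.append(
            {
                "gene": gene,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "lfc": log2_fold_change(xa.mean(), xb.mean(), config.pseudocount),
                "variance_p": res.variance_p,
                "branch": res.branch,
                "t": res.t,
                "p_raw": res.p,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    p_class = out["p_adj"] if config.use_adjusted_p_for_class else out["p_raw"]
    out["class"] = [
        NS if deg else classify_deg(l, p, config)
        for l, p, deg in zip(out["lfc"], p_class, out["degenerate"])
    ]
    out = out[DGE_CSV_COLUMNS + ["degenerate"]]
    out.attrs["config"] = config
    out.attrs["classification_p"] = "p_adj" if config.use_adjusted_p_for_class else "p_raw"
    return out


def volcano_table(results: pd.DataFrame, config: DGEConfig | None = None) -> pd.DataFrame:
    """Volcano-ready table: gene, lfc, -log10 p (classification p), class."""
    config = config or results.attrs.get("config") or DGEConfig()
    p_col = "p_adj" if config.use_adjusted_p_for_class else "p_raw"
    with np.errstate(divide="ignore"):
        neg = -np.log10(results[p_col].to_numpy(float))
    return pd.DataFrame(
        {"gene": results["gene"], "lfc": results["lfc"],
         "neg_log10_p": neg, "class": results["class"]}
    )


def volcano_plot(results: pd.DataFrame, path, config: DGEConfig | None = None,
                 title: str = "") -> None:
    """Save a volcano plot PNG (red = up, blue = down, grey = ns)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or results.attrs.get("config") or DGEConfig()
    vt = volcano_table(results, config)
    colors = {UP: "tab:red", DOWN: "tab:blue", NS: "0.7"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, col in colors.items():
        sub = vt[vt["class"] == cls]
        ax.scatter(sub["lfc"], sub["neg_log10_p"], s=12, c=col, label=cls, alpha=0.8)
    ax.axhline(-np.log10(config.p_threshold), ls="--", lw=0.8, c="0.4")
    for x in (-config.lfc_threshold, config.lfc_threshold):
        ax.axvline(x, ls="--", lw=0.8, c="0.4")
    ax.set_xlabel("LG2FC")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def over_representation(
    hits: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    p_threshold: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test.

    For each named set S the upper-tail probability of drawing at least the
    observed ``|hits ∩ S|`` members of S in ``|hits|`` draws from the
    universe is computed.  A set is significant when p < ``p_threshold``
    **and** the overlap exceeds one gene (the gene-count rule).

    Raises
    ------
    ValueError
        If any hit lies outside the universe.
    """
    hits = set(hits)
    universe = set(universe)
    stray = hits - universe
    if stray:
        raise ValueError(f"hits outside universe: {sorted(stray)}")
    M, N = len(universe), len(hits)
    rows = []
    for name, members in gene_sets.items():
        s = set(members) & universe
        k = len(hits & s)
        p = float(stats.hypergeom.sf(k - 1, M, len(s), N)) if k > 0 else 1.0
        rows.append(
            {"set": name, "set_size": len(s), "overlap": k, "p": min(p, 1.0),
             "significant": bool(p < p_threshold and k >= min_overlap)}
        )
    return pd.DataFrame(rows)


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read gene sets from a text file, one set per line:
    ``set_name<TAB>gene1,gene2,...``."""
    sets: dict[str, set[str]] = {}
    for i, line in enumerate(open(path), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, genes = line.split("\t", 1)
        except ValueError:
            raise ValueError(f"{path}: line {i}: expected 'name<TAB>gene1,gene2,...'")
        sets[name] = {g.strip() for g in genes.split(",") if g.strip()}
    return sets
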