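"""Transcript-level quantification: ddCt qPCR and NB differential expression.

The differential-expression stage is an in-house negative-binomial Wald
test with the filtering logic used throughout the study: a gene is called
up-regulated iff raw p < 0.01, log2FC >= 0.58 (1.5-fold) and BH FDR < 0.1
(down-regulation symmetric). Library sizes are normalised by
median-of-ratios; per-gene NB dispersions come from a method-of-moments
estimate shrunk toward a mean-dispersion trend — with 2-3 replicates the
per-gene estimate alone is far too noisy.

The three-contrast comparison (condensed vs control, diffuse vs control,
condensed vs diffuse) isolates genes regulated by phase separation itself
rather than by the protein's presence; the headline summary is the
fraction of protein-responsive up-genes that are *further* up-regulated by
condensate formation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_P = 0.01
DEFAULT_LFC = 0.58
DEFAULT_FDR = 0.1


# ---------------------------------------------------------------------------
# ddCt
# ---------------------------------------------------------------------------


@dataclass
class QpcrResult:
    """Per-target relative quantification. ``table`` columns: gene, ddct,
    relative_expression, percent_change, p_value."""

    table: pd.DataFrame
    reference_gene: str
    control_condition: str

    def percent_decrease(self, gene: str) -> float:
        rel = float(self.table.set_index("gene").loc[gene, "relative_expression"])
        return 100.0 * (1.0 - rel)


def ddct(ct_table: pd.DataFrame, target_genes, reference_gene: str,
         control_condition: str) -> QpcrResult:
    """Relative expression by the 2^(-ddCt) method with a single reference.

    dCt = Ct_target - Ct_reference per sample; ddCt = mean dCt(test) -
    mean dCt(control); relative expression = 2^(-ddCt) (amplification
    efficiency fixed at 2). A Welch t-test on the per-replicate dCt values
    supplies a p-value per target.
    """
    tbl = pd.DataFrame(ct_table)
    need = {"sample", "condition", "gene", "ct"}
    if not need <= set(tbl.columns):
        raise ValueError(f"ct table must have columns {sorted(need)}")
    if reference_gene not in set(tbl["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} missing from table")
    conditions = tbl["condition"].unique()
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} missing")
    test_conditions = [c for c in conditions if c != control_condition]
    if len(test_conditions) != 1:
        raise ValueError("expected exactly one non-control condition")
    test_condition = test_conditions[0]

    ref = tbl[tbl["gene"] == reference_gene].set_index("sample")["ct"]
    rows = []
    for gene in target_genes:
        sub = tbl[tbl["gene"] == gene]
        if sub.empty:
            raise ValueError(f"target gene {gene!r} missing from table")
        dct = sub.set_index("sample")["ct"] - ref
        cond = sub.set_index("sample")["condition"]
        d_test = dct[cond == test_condition]
        d_ctrl = dct[cond == control_condition]
        if len(d_test) < 2 or len(d_ctrl) < 2:
            raise ValueError("need >= 2 replicates per condition")
        ddct_val = float(d_test.mean() - d_ctrl.mean())
        rel = 2.0 ** (-ddct_val)
        p = float(stats.ttest_ind(d_test, d_ctrl, equal_var=False).pvalue)
        rows.append(dict(gene=gene, ddct=ddct_val, relative_expression=rel,
                         percent_change=100.0 * (rel - 1.0), p_value=p))
    return QpcrResult(table=pd.DataFrame(rows), reference_gene=reference_gene,
                      control_condition=control_condition)


# ---------------------------------------------------------------------------
# NB differential expression
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """Per-gene DE table. ``table`` (indexed by gene): mean_control,
    mean_test, log2fc, p_value, fdr, call in {up, down, ns}."""

    table: pd.DataFrame
    test_condition: str
    control_condition: str
    thresholds: dict

    def genes(self, call: str) -> set:
        return set(self.table.index[self.table["call"] == call])

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (geometric-mean reference)."""
    mat = counts.to_numpy(float)
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene with positive counts in every sample")
    logg = np.log(mat[pos]).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(mat[pos]) - logg, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _trended_dispersion(mu: np.ndarray, disp_raw: np.ndarray,
                        gene_weight: float = 0.1) -> np.ndarray:
    """Shrink raw MoM dispersions toward a trend disp ~ a/mu + b.

    The trend is fitted by least squares on all genes (including negative
    raw estimates — dropping them would bias the trend upward); the
    returned dispersion is a convex combination of the gene estimate and
    the trend value. The gene weight is small because a MoM estimate from
    2-3 replicates is extremely noisy; most of the information is in the
    mean-dispersion trend.
    """
    ok = np.isfinite(disp_raw) & (mu > 0)
    if ok.sum() >= 10:
        X = np.column_stack([1.0 / mu[ok], np.ones(int(ok.sum()))])
        coef, *_ = np.linalg.lstsq(X, disp_raw[ok], rcond=None)
        trend = np.clip(coef[0] / np.clip(mu, 1e-8, None) + coef[1], 1e-8, None)
    else:
        fallback = float(np.median(disp_raw[ok])) if ok.any() else 0.01
        trend = np.full_like(mu, max(fallback, 1e-8))
    return gene_weight * np.clip(disp_raw, 0.0, None) + (1.0 - gene_weight) * trend


def de_test(
    counts: pd.DataFrame,
    design,
    test_condition: str | None = None,
    control_condition: str | None = None,
    p_threshold: float = DEFAULT_P,
    lfc_threshold: float = DEFAULT_LFC,
    fdr_threshold: float = DEFAULT_FDR,
    dispersion: float | None = None,
    prior_count: float = 0.5,
) -> DEResult:
    """NB Wald test for one two-condition contrast.

    counts: integer matrix, genes x samples. design: mapping sample ->
    condition (Series/dict). If the contrast is not named explicitly the
    design must contain exactly two conditions (test = the one that is not
    the control; with no hint, the second in sorted order is the test).
    ``dispersion`` fixes the NB dispersion for all genes (bypassing
    estimation) — useful for oracle comparisons.

    All-zero genes are dropped before testing; BH adjustment runs across
    all tested genes. Calls follow the threshold triple (raw p, |log2FC|,
    FDR).
    """
    design = pd.Series(design)
    counts = counts[design.index]  # align column order
    conditions = sorted(design.unique())
    if test_condition is None or control_condition is None:
        if len(conditions) != 2:
            raise ValueError("specify test/control conditions for multi-condition designs")
        control_condition = control_condition or conditions[0]
        test_condition = test_condition or [c for c in conditions if c != control_condition][0]
    samples_t = design.index[design == test_condition]
    samples_c = design.index[design == control_condition]
    if len(samples_t) < 2 or len(samples_c) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if not np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
        raise ValueError("counts must be integers (raw counts, not TPM)")
    # all-zero filter over the full design, so every contrast drawn from
    # the same experiment shares one gene universe
    nonzero = counts.sum(axis=1) > 0
    mat = counts.loc[nonzero, list(samples_t) + list(samples_c)]
    sf = size_factors(mat)
    norm = mat / sf

    nt, nc = len(samples_t), len(samples_c)
    xt = norm[samples_t].to_numpy(float)
    xc = norm[samples_c].to_numpy(float)
    mu_t, mu_c = xt.mean(axis=1), xc.mean(axis=1)
    mu_pool = (xt.sum(axis=1) + xc.sum(axis=1)) / (nt + nc)

    if dispersion is not None:
        disp = np.full(mat.shape[0], float(dispersion))
    else:
        # pooled within-condition MoM: disp = (var - mu) / mu^2
        var_w = (xt.var(axis=1, ddof=1) * (nt - 1) + xc.var(axis=1, ddof=1) * (nc - 1)) / (nt + nc - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp_raw = (var_w - mu_pool) / np.clip(mu_pool, 1e-8, None) ** 2
        disp_raw = np.nan_to_num(disp_raw, nan=0.0, posinf=0.0)
        disp = _trended_dispersion(mu_pool, disp_raw)

    lfc = np.log2((mu_t + prior_count) / (mu_c + prior_count))
    # delta method: var(log mean) = (1/mu + disp) / n per condition
    v_t = (1.0 / np.clip(mu_t, prior_count, None) + disp) / nt
    v_c = (1.0 / np.clip(mu_c, prior_count, None) + disp) / nc
    se_ln = np.sqrt(v_t + v_c)
    # with trend-dominated dispersion the variance is effectively known,
    # so the Wald statistic is referred to the standard normal
    z = lfc * np.log(2.0) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]

    call = np.full(mat.shape[0], "ns", dtype=object)
    up = (p < p_threshold) & (lfc >= lfc_threshold) & (fdr < fdr_threshold)
    down = (p < p_threshold) & (lfc <= -lfc_threshold) & (fdr < fdr_threshold)
    call[up], call[down] = "up", "down"

    table = pd.DataFrame(dict(mean_control=mu_c, mean_test=mu_t, log2fc=lfc,
                              dispersion=disp, p_value=p, fdr=fdr, call=call),
                         index=mat.index)
    return DEResult(table=table, test_condition=test_condition,
                    control_condition=control_condition,
                    thresholds=dict(p=p_threshold, lfc=lfc_threshold, fdr=fdr_threshold))


# ---------------------------------------------------------------------------
# contrasts and enrichment
# ---------------------------------------------------------------------------


@dataclass
class DEGComparison:
    """Set algebra over the three study contrasts."""

    up: dict[str, set]
    down: dict[str, set]
    intersections: dict[str, int]
    further_enhanced_fraction_pct: float  # of condensed-vs-control up genes,
    # the share also up in condensed-vs-diffuse


def compare_contrasts(de_results: dict[str, DEResult],
                      primary: str | None = None,
                      ps_contrast: str | None = None) -> DEGComparison:
    """Compare DEG sets across contrasts sharing one gene universe.

    ``primary`` names the protein-vs-control contrast and ``ps_contrast``
    the condensed-vs-diffuse contrast (defaults: first and last key). The
    headline number is the percentage of primary up-genes that are further
    up-regulated in the PS contrast.
    """
    names = list(de_results)
    if len(names) < 2:
        raise ValueError("need >= 2 contrasts to compare")
    universes = {frozenset(r.table.index) for r in de_results.values()}
    if len(universes) > 1:
        raise ValueError("contrasts use different gene universes")
    primary = primary or names[0]
    ps_contrast = ps_contrast or names[-1]
    up = {n: r.genes("up") for n, r in de_results.items()}
    down = {n: r.genes("down") for n, r in de_results.items()}
    inter = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter[f"{a}&{b}_up"] = len(up[a] & up[b])
            inter[f"{a}&{b}_down"] = len(down[a] & down[b])
    n_primary_up = len(up[primary])
    frac = (100.0 * len(up[primary] & up[ps_contrast]) / n_primary_up
            if n_primary_up else float("nan"))
    return DEGComparison(up=up, down=down, intersections=inter,
                         further_enhanced_fraction_pct=frac)


def enrichment_test(deg_set, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    p = P(X >= k) with X ~ Hypergeom(M=|universe|, K=|set|, n=|deg|);
    BH-adjusted across sets. All sets must be subsets of the universe.
    """
    universe = set(universe)
    deg = set(deg_set)
    if not deg <= universe:
        raise ValueError("DEG set is not a subset of the universe")
    rows = []
    for name, gs in gene_sets.items():
        gs = set(gs)
        if not gs <= universe:
            raise ValueError(f"gene set {name!r} is not a subset of the universe")
        k = len(deg & gs)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(gs), len(deg)))
        rows.append(dict(gene_set=name, n_set=len(gs), n_overlap=k, p_value=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
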