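"""Temporal co-expression of interacting proteins and hub classification.

Co-expression of an interacting pair is the Pearson correlation (PCC) of
the two genes' circadian expression profiles.  Interacting pairs are tested
for enrichment of co-expressed pairs (PCC > 0.5, strict) against randomly
drawn gene pairs with a 2x2 chi-squared test.

Hubs are classified in the party/date scheme: a hub whose partners are
co-expressed with it around the clock is a *party hub* (mean partner PCC
significantly above random partner sets), one whose interactions are
spread over different times a *date hub* (significantly below).  The
background is the mean PCC of random partner sets of equal size; the
"partially random" variant keeps a random half of the true partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import InteractionNetwork

__all__ = [
    "pair_pcc",
    "CoexpressionEnrichment",
    "coexpression_enrichment",
    "HubClassification",
    "classify_hub",
    "classify_hubs",
    "degree_vs_rhythmicity_tests",
    "rhythmicity_enrichment",
]

PCC_COEXPRESSION_THRESHOLD = 0.5


def _pcc_matrix_rows(values: np.ndarray) -> np.ndarray:
    """Row-standardized copy (population sd) with NaN rows for constants."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    return z


def pair_pcc(expression: pd.DataFrame, pairs) -> pd.DataFrame:
    """Pearson correlation of expression profiles for each gene pair.

    Pairs with a missing gene or a constant profile are flagged
    ``testable=False`` with NaN PCC and are excluded from downstream
    fractions.
    """
    values = expression.to_numpy(dtype=float)
    z = _pcc_matrix_rows(values) / np.sqrt(values.shape[1])
    loc = {str(g): i for i, g in enumerate(expression.index)}
    rows = []
    for a, b in pairs:
        a, b = str(a), str(b)
        ia, ib = loc.get(a), loc.get(b)
        if ia is None or ib is None:
            rows.append({"id_a": a, "id_b": b, "pcc": np.nan, "testable": False})
            continue
        pcc = float(z[ia] @ z[ib])
        ok = np.isfinite(pcc)
        rows.append({"id_a": a, "id_b": b, "pcc": pcc if ok else np.nan, "testable": bool(ok)})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "pcc", "testable"])


@dataclass(frozen=True)
class CoexpressionEnrichment:
    """Observed vs random fraction of co-expressed (PCC>0.5) pairs."""

    observed_fraction: float
    random_fraction: float
    chi2: float
    p: float
    n_observed: int
    n_random: int
    threshold: float


def coexpression_enrichment(
    expression: pd.DataFrame,
    pairs,
    n_random: int = 10000,
    seed: int | np.random.Generator | None = None,
    threshold: float = PCC_COEXPRESSION_THRESHOLD,
) -> CoexpressionEnrichment:
    """Chi-squared enrichment of co-expressed pairs among interactions.

    Random pairs are drawn uniformly from the genes present in the matrix,
    excluding the true interacting pairs; the 2x2 table counts pairs above
    vs not-above ``threshold`` (strictly greater counts as co-expressed).
    """
    if n_random < 1000:
        raise ValueError("need at least 1000 random pairs")
    genes = [str(g) for g in expression.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes with profiles")
    rng = np.random.default_rng(seed)
    true_pairs = {tuple(sorted((str(a), str(b)))) for a, b in pairs}

    obs = pair_pcc(expression, pairs)
    obs = obs[obs["testable"]]
    if len(obs) == 0:
        raise ValueError("no testable interacting pairs")

    random_pairs = []
    while len(random_pairs) < n_random:
        idx = rng.integers(0, len(genes), size=(n_random, 2))
        for i, j in idx:
            if i == j:
                continue
            pr = tuple(sorted((genes[i], genes[j])))
            if pr in true_pairs:
                continue
            random_pairs.append(pr)
            if len(random_pairs) == n_random:
                break
    rnd = pair_pcc(expression, random_pairs)
    rnd = rnd[rnd["testable"]]

    obs_hi = int((obs["pcc"] > threshold).sum())
    rnd_hi = int((rnd["pcc"] > threshold).sum())
    table = np.array(
        [[obs_hi, len(obs) - obs_hi], [rnd_hi, len(rnd) - rnd_hi]], dtype=float
    )
    if (table.sum(axis=0) == 0).any():  # degenerate margin: no evidence either way
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.chi2_contingency(table, correction=False)[:2]
    return CoexpressionEnrichment(
        observed_fraction=obs_hi / len(obs),
        random_fraction=rnd_hi / len(rnd),
        chi2=float(chi2),
        p=float(p),
        n_observed=len(obs),
        n_random=len(rnd),
        threshold=threshold,
    )


@dataclass(frozen=True)
class HubClassification:
    """Party/date classification of one hub protein."""

    protein: str
    degree: int
    mean_partner_pcc: float
    fdr_high: float  # empirical FDR for "higher PCC than chance"
    fdr_low: float  # empirical FDR for "lower PCC than chance"
    label: str  # "party" | "date" | "unclassified"


def classify_hub(
    protein: str,
    net: InteractionNetwork,
    expression: pd.DataFrame,
    n_background: int = 1000,
    seed: int | np.random.Generator | None = None,
    fdr: float = 0.01,
    background: str = "random",
) -> HubClassification:
    """Classify a hub as party or date hub via random partner sets.

    The hub's observed mean PCC with its profiled partners is compared with
    ``n_background`` random partner sets of equal size drawn from the
    profiled genes (hub excluded).  ``background="partial"`` retains a
    uniformly chosen half of the true partners in every background set.
    Empirical FDRs use the add-one convention; party if ``fdr_high < fdr``,
    date if ``fdr_low < fdr``.
    """
    if background not in ("random", "partial"):
        raise ValueError("background must be 'random' or 'partial'")
    rng = np.random.default_rng(seed)
    genes = [str(g) for g in expression.index]
    loc = {g: i for i, g in enumerate(genes)}
    if protein not in loc:
        raise ValueError(f"hub {protein} has no expression profile")
    values = expression.to_numpy(dtype=float)
    z = _pcc_matrix_rows(values) / np.sqrt(values.shape[1])
    if not np.all(np.isfinite(z[loc[protein]])):
        raise ValueError(f"hub {protein} profile is constant")

    partners = [p for p in net.neighbors(protein) if p in loc and np.all(np.isfinite(z[loc[p]]))]
    if len(partners) < 2:
        raise ValueError(f"hub {protein} has fewer than 2 profiled partners")
    k = len(partners)
    zh = z[loc[protein]]
    observed = float(np.mean([zh @ z[loc[p]] for p in partners]))

    pool = np.array([i for g, i in loc.items() if g != protein and np.all(np.isfinite(z[i]))])
    if len(pool) < k:
        raise ValueError("not enough profiled genes for background sets")
    partner_idx = np.array([loc[p] for p in partners])
    bg = np.empty(n_background)
    for b in range(n_background):
        if background == "partial":
            keep = rng.choice(partner_idx, size=k // 2, replace=False)
            rest = rng.choice(pool, size=k - len(keep), replace=False)
            sel = np.concatenate([keep, rest])
        else:
            sel = rng.choice(pool, size=k, replace=False)
        bg[b] = float(np.mean(z[sel] @ zh))

    fdr_high = (1 + np.count_nonzero(bg >= observed)) / (n_background + 1)
    fdr_low = (1 + np.count_nonzero(bg <= observed)) / (n_background + 1)
    if fdr_high < fdr and fdr_high <= fdr_low:
        label = "party"
    elif fdr_low < fdr:
        label = "date"
    else:
        label = "unclassified"
    return HubClassification(
        protein=protein,
        degree=int(net.degree()[protein]),
        mean_partner_pcc=observed,
        fdr_high=float(fdr_high),
        fdr_low=float(fdr_low),
        label=label,
    )


def classify_hubs(
    net: InteractionNetwork,
    expression: pd.DataFrame,
    hub_threshold: int = 20,
    n_background: int = 1000,
    seed: int | None = None,
    fdr: float = 0.01,
    background: str = "random",
) -> pd.DataFrame:
    """Classify every hub (degree >= threshold) with a profiled partner set."""
    rng = np.random.default_rng(seed)
    deg = net.degree()
    rows = []
    for protein in sorted(deg.index[deg >= hub_threshold]):
        try:
            c = classify_hub(protein, net, expression, n_background, rng, fdr, background)
        except ValueError:
            continue
        rows.append(vars(c))
    return pd.DataFrame(
        rows, columns=["protein", "degree", "mean_partner_pcc", "fdr_high", "fdr_low", "label"]
    )


@dataclass(frozen=True)
class DegreeRhythmicityTests:
    """Association between connectivity and rhythmic expression."""

    wilcoxon_statistic: float
    wilcoxon_p: float
    chi2: float
    chi2_p: float
    degree_cut: float
    n_rhythmic: int
    n_nonrhythmic: int


def degree_vs_rhythmicity_tests(
    net: InteractionNetwork,
    rhythm_results: pd.DataFrame,
    degree_cut: float | None = None,
) -> DegreeRhythmicityTests:
    """Two complementary tests linking degree and rhythmicity.

    (a) Wilcoxon rank-sum of degree between rhythmic and non-rhythmic
    network proteins; (b) chi-squared of the rhythmic fraction between
    high- and low-degree strata, cut at the median degree by default.
    """
    deg = net.degree()
    calls = rhythm_results.loc[rhythm_results.index.intersection(deg.index), "is_rhythmic"]
    if len(calls) == 0:
        raise ValueError("no rhythm calls for network genes")
    deg = deg.loc[calls.index]
    rhythmic = calls.astype(bool)
    d_r = deg[rhythmic]
    d_n = deg[~rhythmic]
    if len(d_r) == 0 or len(d_n) == 0:
        raise ValueError("one rhythmicity stratum is empty")
    w_stat, w_p = stats.ranksums(d_r, d_n)

    cut = float(deg.median()) if degree_cut is None else float(degree_cut)
    high = rhythmic[deg > cut]
    low = rhythmic[deg <= cut]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("one degree stratum is empty")
    table = np.array(
        [[high.sum(), len(high) - high.sum()], [low.sum(), len(low) - low.sum()]],
        dtype=float,
    )
    chi2, chi2_p = stats.chi2_contingency(table, correction=False)[:2]
    return DegreeRhythmicityTests(
        wilcoxon_statistic=float(w_stat),
        wilcoxon_p=float(w_p),
        chi2=float(chi2),
        chi2_p=float(chi2_p),
        degree_cut=cut,
        n_rhythmic=int(rhythmic.sum()),
        n_nonrhythmic=int((~rhythmic).sum()),
    )


def rhythmicity_enrichment(
    rhythm_results: pd.DataFrame, subset_genes
) -> tuple[float, float, float, float]:
    """Chi-squared enrichment of rhythmic genes in a subset vs the matrix.

    Returns (subset_fraction, background_fraction, chi2, p); the background
    is all genes in the rhythm table outside the subset.
    """
    subset = {str(g) for g in subset_genes}
    in_sub = rhythm_results.index.astype(str).isin(subset)
    calls = rhythm_results["is_rhythmic"].astype(bool).to_numpy()
    a, b = calls[in_sub].sum(), (~calls[in_sub]).sum()
    c, d = calls[~in_sub].sum(), (~calls[~in_sub]).sum()
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("subset or background empty")
    chi2, p = stats.chi2_contingency(
        np.array([[a, b], [c, d]], dtype=float), correction=False
    )[:2]
    return float(a / (a + b)), float(c / (c + d)), float(chi2), float(p)
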