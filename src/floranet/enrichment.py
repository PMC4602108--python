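"""Per-module term over-representation and kappa term grouping.

Each module is tested for term over-representation with the upper-tail
hypergeometric probability, Bonferroni-corrected over the terms actually
tested; terms with corrected P below the reporting threshold (default
0.005) are flagged. Flagged or tested terms are then linked by Cohen's
kappa over their gene memberships (threshold 0.3) and merged into
functional groups by iterating a shared-terms rule to a fixpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import EnrichmentParams


@dataclass
class AnnotationSet:
    """Term -> gene-set annotations restricted to an analysis universe."""

    universe: set[str]
    terms: dict[str, set[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        dropped = 0
        for term, genes in self.terms.items():
            inside = set(genes) & self.universe
            dropped += len(genes) - len(inside)
            if inside:
                cleaned[term] = inside
        if dropped:
            warnings.warn(
                f"dropped {dropped} annotations outside the analysis universe",
                stacklevel=2,
            )
        self.terms = cleaned


def hypergeom_overrep(
    module_genes: set[str], term_genes: set[str], universe: set[str]
) -> float:
    """Upper-tail probability P(X >= x) for the module/term overlap.

    X follows Hypergeometric(N=|universe|, K=|term|, n=|module|) and x is
    the observed overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    n_universe = len(universe)
    k_term = len(term_genes & universe)
    n_module = len(module_genes)
    x = len(module_genes & term_genes)
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, n_universe, k_term, n_module))


def correct_and_flag(
    results: pd.DataFrame,
    m_tests: int,
    alpha_raw: float = 0.05,
    alpha_corrected: float = 0.005,
) -> pd.DataFrame:
    """Bonferroni-correct raw p-values and flag over-represented terms.

    Adds ``p_bonferroni = min(1, p_raw * m_tests)``, the raw-significance
    column at ``alpha_raw``, and the over-representation flag at
    ``alpha_corrected``.
    """
    out = results.copy()
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * m_tests)
    out["raw_significant"] = out["p_raw"] < alpha_raw
    out["overrepresented"] = out["p_bonferroni"] < alpha_corrected
    return out


def enrich_module(
    module_genes: set[str],
    annotations: AnnotationSet,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Test every eligible term against one module.

    Terms overlapping the module in fewer than ``min_overlap`` genes are
    skipped before testing, and the Bonferroni factor counts only the
    tested terms.
    """
    params = params or EnrichmentParams()
    universe = annotations.universe
    module_genes = set(module_genes) & universe
    rows = []
    for term in sorted(annotations.terms):
        genes = annotations.terms[term]
        x = len(module_genes & genes)
        if x < params.min_overlap:
            continue
        rows.append(
            {
                "term": term,
                "x": x,
                "n": len(module_genes),
                "K": len(genes),
                "N": len(universe),
                "p_raw": hypergeom_overrep(module_genes, genes, universe),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "x", "n", "K", "N", "p_raw"])
    return correct_and_flag(
        table, m_tests=max(1, len(table)),
        alpha_raw=params.alpha_raw, alpha_corrected=params.alpha_corrected,
    )


# ---------------------------------------------------------------------------
# kappa grouping


def cohen_kappa(term_a: set[str], term_b: set[str], universe: set[str]) -> float:
    """Chance-corrected agreement of two gene memberships over the universe."""
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    a = len(term_a & term_b)
    b = len(term_a - term_b)
    c = len(term_b - term_a)
    d = n - a - b - c
    p_o = (a + d) / n
    p_yes = ((a + b) / n) * ((a + c) / n)
    p_no = ((c + d) / n) * ((b + d) / n)
    p_e = p_yes + p_no
    if p_e >= 1.0:
        warnings.warn("degenerate memberships (p_e = 1); kappa set to 0", stacklevel=2)
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_matrix(
    terms: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Symmetric kappa matrix over the given terms."""
    if len(terms) < 2:
        raise ValueError("need at least 2 terms")
    names = sorted(terms)
    k = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            k[i, j] = k[j, i] = cohen_kappa(terms[a], terms[names[j]], universe)
    return pd.DataFrame(k, index=names, columns=names)


def group_terms(kappa: pd.DataFrame, threshold: float = 0.3) -> pd.Series:
    """Merge kappa-linked term pairs into functional groups.

    Every term pair with kappa >= threshold seeds an initial group; two
    groups merge when they share at least half of the smaller group's
    terms, iterated to a fixpoint. Terms in no linked pair form singleton
    groups. Group ids are assigned canonically by each group's
    lexicographically smallest term, so the result is independent of
    processing order.
    """
    names = list(kappa.index)
    groups: list[set[str]] = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            if kappa.iloc[i, j] >= threshold:
                groups.append({a, names[j]})
    changed = True
    while changed:
        changed = False
        groups.sort(key=lambda g: sorted(g))
        merged: list[set[str]] = []
        for g in groups:
            target = None
            for h in merged:
                smaller = min(len(g), len(h))
                if len(g & h) >= 0.5 * smaller:
                    target = h
                    break
            if target is None:
                merged.append(set(g))
            else:
                if not g <= target:
                    changed = True
                target |= g
        groups = merged
    grouped = {t for g in groups for t in g}
    for t in names:
        if t not in grouped:
            groups.append({t})
    groups.sort(key=lambda g: min(g))
    assignment: dict[str, int] = {}
    for gid, g in enumerate(groups):
        for t in sorted(g):
            if t not in assignment:  # a term stays with its first canonical group
                assignment[t] = gid
    return pd.Series(assignment, name="kappa_group").loc[names]


def enrich_partition(
    module_members: dict[str, set[str]],
    annotations: AnnotationSet,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Enrichment table over all modules with kappa group assignments.

    With ``global_correction`` the Bonferroni factor counts the tests over
    all modules instead of per module.
    """
    params = params or EnrichmentParams()
    frames = []
    for module in sorted(module_members):
        table = enrich_module(module_members[module], annotations, params)
        table.insert(0, "module", module)
        frames.append(table)
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if combined.empty:
        return combined
    if params.global_correction:
        combined = combined.drop(columns=["p_bonferroni", "raw_significant", "overrepresented"])
        combined = correct_and_flag(
            combined, m_tests=len(combined),
            alpha_raw=params.alpha_raw, alpha_corrected=params.alpha_corrected,
        )
    tested_terms = sorted(set(combined["term"]))
    if len(tested_terms) >= 2:
        terms = {t: annotations.terms[t] for t in tested_terms}
        kappa = kappa_matrix(terms, annotations.universe)
        group = group_terms(kappa, params.kappa_threshold)
        combined["kappa_group"] = combined["term"].map(group)
    else:
        combined["kappa_group"] = 0
    return combined
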