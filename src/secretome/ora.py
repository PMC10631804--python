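"""Over-representation analysis of protein subsets against GO annotations.

The kinetic classification is validated by asking whether the secreted set is
enriched for extracellular cellular-component terms relative to the full
identified background (in the motivating study, all proteins seen at every
labeling time point).  Per term the one-sided hypergeometric tail

    p = P(X >= k),  X ~ Hypergeom(N = background, K = annotated, n = selected)

is computed, followed by Benjamini-Hochberg step-up adjustment across the
tested terms.
"""

from __future__ import annotations

import re
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "hypergeom_tail", "read_annotations", "hypergeom_enrich"]

_GO_PATTERN = re.compile(r"^GO:\d{7}$")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_tail(k: int, n_background: int, k_annotated: int, n_selected: int) -> float:
    """One-sided upper tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not 0 <= k_annotated <= n_background or not 0 <= n_selected <= n_background:
        raise ValueError("annotated and selected counts must not exceed background")
    return float(min(hypergeom.sf(k - 1, n_background, k_annotated, n_selected), 1.0))


def read_annotations(path, validate_go: bool = True) -> pd.DataFrame:
    """Read a two-column (protein_id, term) TSV, optional third column namespace."""
    annot = pd.read_csv(path, sep="\t", dtype=str, header=0)
    cols = list(annot.columns[:3])
    rename = dict(zip(cols, ["protein_id", "term", "namespace"][: len(cols)]))
    annot = annot.rename(columns=rename)
    if validate_go:
        bad = annot.loc[~annot["term"].astype(str).str.match(_GO_PATTERN), "term"]
        if len(bad):
            raise ValueError(
                f"malformed GO term id(s): {', '.join(sorted(set(bad))[:5])}"
            )
    return annot


def hypergeom_enrich(
    selected: Iterable[str],
    background: Iterable[str],
    annotations: pd.DataFrame,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within ``background``.

    Only terms annotating at least one background protein are tested; the BH
    family is the set of tested terms, per namespace when the annotation
    table carries one.  No GO-graph propagation is performed: a protein
    counts toward exactly the terms it is directly annotated with.

    Returns a frame sorted by p-value with columns ``term``, ``term_name``,
    ``namespace``, ``k_selected``, ``n_selected``, ``K_annotated``,
    ``N_background``, ``p_value``, ``q_value``.
    """
    selected = set(map(str, selected))
    background = set(map(str, background))
    if not selected <= background:
        extra = sorted(selected - background)[:5]
        raise ValueError(f"selected proteins outside background: {', '.join(extra)}")

    annot = annotations.loc[annotations["protein_id"].isin(background)].copy()
    if "namespace" not in annot.columns:
        annot["namespace"] = "CC"
    n_sel, n_bg = len(selected), len(background)

    rows = []
    for (term, namespace), sub in annot.groupby(["term", "namespace"]):
        members = set(sub["protein_id"])
        k_annotated = len(members)
        k_sel = len(members & selected)
        p = hypergeom_tail(k_sel, n_bg, k_annotated, n_sel)
        rows.append(
            {
                "term": term,
                "term_name": (term_names or {}).get(term, ""),
                "namespace": namespace,
                "k_selected": k_sel,
                "n_selected": n_sel,
                "K_annotated": k_annotated,
                "N_background": n_bg,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["q_value"] = []
        return result
    result["q_value"] = np.nan
    for _, idx in result.groupby("namespace").groups.items():
        result.loc[idx, "q_value"] = bh_adjust(result.loc[idx, "p_value"])
    return result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
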