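"""Hypergeometric ontology analysis with frequency-weighted aggregation.

Per-term enrichment of a query gene set against a GMT collection is the
standard upper-tail hypergeometric test (P[X >= overlap]), corrected across
the tested terms (Benjamini-Hochberg by default). Terms are then aggregated
into named subgroups as a weighted arithmetic mean of corrected p-values,
with weights proportional to how often each constituent ontology class
appeared in the query (number of annotated query genes) or uniform. The
fold-frequency ratio of two aggregated probabilities is the descriptive
quotient used to compare how frequently a molecular process occurs between
two conditions: the condition with the smaller probability is the more
frequent one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_enrich",
    "weighted_summary",
    "fold_frequency",
]

_CORRECTIONS = {"bh": "fdr_bh", "bonferroni": "bonferroni", "none": None}


def hypergeom_enrich(
    query,
    terms: dict[str, set[str]],
    universe,
    correction: str = "bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    Returns one row per term: overlap, term_size (after intersection with
    the universe), query_size, universe_size, p_raw, p_corrected.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in terms.items():
        members = genes & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "query_size": n,
                "universe_size": N,
                "p_raw": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "overlap", "term_size", "query_size", "universe_size", "p_raw"],
    )
    if out.empty:
        out["p_corrected"] = pd.Series(dtype=float)
        return out
    method = _CORRECTIONS[correction]
    if method is None:
        out["p_corrected"] = out["p_raw"]
    else:
        out["p_corrected"] = multipletests(out["p_raw"].to_numpy(), method=method)[1]
    return out


def weighted_summary(
    records: pd.DataFrame,
    grouping: dict[str, str],
    weight_mode: str = "term_frequency",
) -> pd.DataFrame:
    """Aggregate per-term corrected p-values into subgroup probabilities.

    ``grouping`` maps term -> subgroup label. ``weight_mode``:

    * ``term_frequency`` (default): weight proportional to the number of
      query genes annotated to the term (its appearance frequency in the
      analysis); subgroups whose terms all have zero overlap fall back to
      uniform weights;
    * ``uniform``: plain average.

    Subgroups with no scored term are dropped. The weighted mean always lies
    within [min, max] of the member corrected p-values.
    """
    if weight_mode not in ("term_frequency", "uniform"):
        raise ValueError("weight_mode must be 'term_frequency' or 'uniform'")
    recs = records.set_index("term")
    rows = []
    subgroups: dict[str, list[str]] = {}
    for term, sub in grouping.items():
        subgroups.setdefault(sub, []).append(term)
    for sub, term_list in subgroups.items():
        present = [t for t in term_list if t in recs.index]
        if not present:
            continue  # no records for this subgroup
        p = recs.loc[present, "p_corrected"].to_numpy(dtype=float)
        if weight_mode == "term_frequency":
            w = recs.loc[present, "overlap"].to_numpy(dtype=float)
            if w.sum() == 0:
                w = np.ones_like(p)
        else:
            w = np.ones_like(p)
        w = w / w.sum()
        rows.append(
            {
                "subgroup": sub,
                "n_terms": len(present),
                "weighted_p": float(np.sum(w * p)),
                "member_terms": ";".join(present),
            }
        )
    return pd.DataFrame(rows, columns=["subgroup", "n_terms", "weighted_p", "member_terms"])


def fold_frequency(p_a: float, p_b: float) -> tuple[float, str]:
    """Quotient of two aggregated probabilities, oriented to the smaller p.

    Returns ``(ratio >= 1, orientation)`` where orientation names the more
    frequent condition: ``"a"`` when ``p_a < p_b``, ``"b"`` when
    ``p_b < p_a``, ``"equal"`` otherwise. The full-precision ratio is
    returned; round to 2 significant figures for display.
    """
    for p in (p_a, p_b):
        if not (0 < p <= 1):
            raise ValueError("probabilities must be in (0, 1]")
    if p_a == p_b:
        return 1.0, "equal"
    ratio = max(p_a, p_b) / min(p_a, p_b)
    return float(ratio), "a" if p_a < p_b else "b"
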