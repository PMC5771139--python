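"""Fisher-exact (hypergeometric) gene-set over-representation analysis.

The test is one-sided over-representation against a user-supplied universe:
the defensible background for a proteomics experiment is the set of
*quantified* proteins, not the genome, because only quantified proteins
could ever have entered the foreground.  Gene symbols are matched
case-insensitively across the abundance tables and the GMT file.
"""

from __future__ import annotations

from typing import Iterable


import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .datatypes import AnnotationSets


def fisher_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    sets: AnnotationSets,
    p_cutoff: float = 0.01,
    adjust: bool = False,
) -> pd.DataFrame:
    """Over-representation p-value per annotation term.

    For a term with ``K`` members in the background of size ``N`` and ``k``
    members in the foreground of size ``n``, the one-sided Fisher p is the
    hypergeometric upper tail ``P(X >= k)``; fold enrichment is
    ``(k/n) / (K/N)``.  Terms with zero foreground hits are omitted; the
    result is filtered at ``p < p_cutoff`` and sorted by ascending p (ties
    by term id).  ``adjust=True`` adds BH-adjusted p-values computed across
    all terms with at least one foreground hit (before the cutoff filter).

    Raises
    ------
    ValidationError
        If the foreground is not a subset of the background (offenders are
        listed in the message).
    """
    norm = AnnotationSets.normalize
    fg = {norm(s) for s in foreground}
    bg = {norm(s) for s in background}
    stray = sorted(fg - bg)
    if stray:
        raise ValidationError(
            f"{len(stray)} foreground symbols absent from background: {stray[:10]}"
        )
    n, N = len(fg), len(bg)
    rows = []
    for term_id, (term_name, members) in sets.items():
        members_bg = members & bg
        K = len(members_bg)
        k = len(members_bg & fg)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term_id, term_name, k, n, K, N, fold, p))
    frame = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "n", "K", "N",
                 "fold_enrichment", "p_value"],
    )
    if len(frame) == 0:
        if adjust:
            frame["adjusted_p"] = pd.Series(dtype=float)
        return frame
    if adjust:
        from .dep import bh_adjust

        frame["adjusted_p"] = bh_adjust(frame["p_value"].to_numpy())
    frame = frame[frame["p_value"] < p_cutoff]
    frame = frame.sort_values(["p_value", "term_id"], kind="stable")
    return frame.reset_index(drop=True)
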