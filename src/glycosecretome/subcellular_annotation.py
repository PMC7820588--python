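"""Inclusive subcellular binning of proteins from GO Cellular Component terms.

Proteins are placed, inclusively, into twelve compartment categories by
case-insensitive keyword matching on their GO CC term names: plasma
membrane; other membrane (terms containing 'membrane' but not 'plasma
membrane'); neural ('axon', 'neuro', or 'myelin'); ER ('endoplasmic');
Golgi ('golgi' in a term that does not also contain 'endoplasmic'); cell
surface ('surface'); synapse, extracellular, vesicle, lysosome and
secreted (their respective words, with 'secretory' also counted as
secreted); and none listed for proteins matching no other category.
A protein may belong to several categories; ``none_listed`` is always a
singleton assignment.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from glycosecretome.glycan_typing import maturity_order

__all__ = [
    "SUBCELLULAR_CATEGORIES",
    "assign_subcellular",
    "assign_all",
    "location_glycan_summary",
]

logger = logging.getLogger(__name__)

SUBCELLULAR_CATEGORIES = (
    "plasma_membrane",
    "other_membrane",
    "neural",
    "ER",
    "Golgi",
    "cell_surface",
    "synapse",
    "extracellular",
    "vesicle",
    "lysosome",
    "secreted",
    "none_listed",
)

#: Keywords whose presence in a term assigns the simple categories.
_SIMPLE_KEYWORDS = {
    "cell_surface": ("surface",),
    "synapse": ("synapse",),
    "extracellular": ("extracellular",),
    "vesicle": ("vesicle",),
    "lysosome": ("lysosome",),
    "ER": ("endoplasmic",),
    "neural": ("axon", "neuro", "myelin"),
}

DEFAULT_SECRETED_KEYWORDS = ("secreted", "secretory")


def assign_subcellular(
    terms: Iterable[str],
    secreted_keywords: Sequence[str] = DEFAULT_SECRETED_KEYWORDS,
) -> frozenset[str]:
    """Assign a protein's GO CC terms to subcellular categories.

    Matching is case-insensitive substring on term names and inclusive:
    one protein can land in several categories.  The Golgi rule excludes
    terms that also contain 'endoplasmic' (so the ERGIC term counts as ER,
    not Golgi), and the membrane rule splits 'plasma membrane' terms from
    all other 'membrane' terms per term.  Returns ``{"none_listed"}`` when
    nothing matches.
    """
    categories: set[str] = set()
    for term in terms:
        low = term.lower()
        if "plasma membrane" in low:
            categories.add("plasma_membrane")
        if "membrane" in low and "plasma membrane" not in low:
            categories.add("other_membrane")
        if "golgi" in low and "endoplasmic" not in low:
            categories.add("Golgi")
        for category, keywords in _SIMPLE_KEYWORDS.items():
            if any(keyword in low for keyword in keywords):
                categories.add(category)
        if any(keyword in low for keyword in secreted_keywords):
            categories.add("secreted")
    if not categories:
        return frozenset({"none_listed"})
    return frozenset(categories)


def assign_all(
    annotation: Mapping[str, Iterable[str]],
    secreted_keywords: Sequence[str] = DEFAULT_SECRETED_KEYWORDS,
) -> dict[str, frozenset[str]]:
    """Apply :func:`assign_subcellular` to a protein -> GO CC terms map."""
    return {
        protein: assign_subcellular(terms, secreted_keywords=secreted_keywords)
        for protein, terms in annotation.items()
    }


def location_glycan_summary(
    sig: pd.DataFrame,
    assignment: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Cross-tabulate significant glycoforms by subcellular category and glycan type.

    ``sig`` needs columns ``protein_id`` and ``glycan_type``.  Counting is
    inclusive: a glycoform adds one count to every category its protein
    belongs to, so the marginal total of a category equals the number of
    significant glycoforms whose protein carries that category.  Proteins
    absent from ``assignment`` are counted under ``none_listed`` with a
    logged warning.  Returns a category x glycan-type count table covering
    all twelve categories and five types.
    """
    counts = pd.DataFrame(
        0,
        index=pd.Index(SUBCELLULAR_CATEGORIES, name="category"),
        columns=pd.Index(maturity_order(), name="glycan_type"),
    )
    for row in sig.itertuples(index=False):
        protein = row.protein_id
        glycan_type = row.glycan_type
        if protein in assignment:
            categories = assignment[protein]
        else:
            logger.warning("protein %r missing from annotation; counted as none_listed",
                           protein)
            categories = ("none_listed",)
        for category in categories:
            counts.loc[category, glycan_type] += 1
    return counts
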