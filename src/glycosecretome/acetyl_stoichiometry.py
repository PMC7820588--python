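"""Site-level lysine acetylation stoichiometry from light/heavy fragment pairs.

After exhaustive chemical acetylation with D6-acetic anhydride, every lysine
carries either the endogenous (light) acetyl group or a chemically installed
d3-acetyl group, +3.0188304 Da heavier per acetyl.  The occupancy of a site
by endogenous acetylation is then the ratio of the light fragment-ion peak
area over the total (light + heavy) area, pooled over all fragment ions and
chromatographic fractions covering that site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "FragmentPair",
    "StoichiometryRecord",
    "D3_ACETYL_MASS_SHIFT",
    "heavy_fragment_mz",
    "site_stoichiometry",
    "aggregate_fractions",
]

logger = logging.getLogger(__name__)

#: Monoisotopic mass difference between d3-acetyl and acetyl:
#: 3 * (m(2H) - m(1H)) = 3 * (2.0141018 - 1.0078250) Da.
D3_ACETYL_MASS_SHIFT = 3.0188304


@dataclass(frozen=True)
class FragmentPair:
    """Light/heavy fragment-ion peak areas for one acetylation site."""

    protein_id: str
    site: int
    fragment_id: str
    fraction: str
    light_area: float
    heavy_area: float
    n_chemical_acetyl: int = 1
    charge: int = 1

    def __post_init__(self) -> None:
        if self.light_area < 0 or self.heavy_area < 0:
            raise ValueError("peak areas must be non-negative")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.n_chemical_acetyl < 0:
            raise ValueError("n_chemical_acetyl must be >= 0")

    @property
    def usable(self) -> bool:
        """A pair is usable when at least one of its areas is positive."""
        return self.light_area + self.heavy_area > 0


@dataclass(frozen=True)
class StoichiometryRecord:
    """Endogenous acetylation occupancy of one site."""

    protein_id: str
    site: int
    stoichiometry: float
    n_fragments: int
    n_fractions: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.stoichiometry <= 1.0:
            raise ValueError("stoichiometry must lie in [0, 1]")
        if self.n_fragments < 1:
            raise ValueError("a record requires at least one fragment")


def heavy_fragment_mz(light_mz: float, n_chemical_acetyl: int, charge: int) -> float:
    """In-silico m/z of the heavy (d3-acetyl) partner of a light fragment ion.

    ``heavy = light + n * 3.0188304 / z`` for ``n`` chemically acetylated
    lysines on the fragment at charge ``z``.
    """
    if light_mz <= 0:
        raise ValueError("light_mz must be positive")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if n_chemical_acetyl < 0:
        raise ValueError("n_chemical_acetyl must be >= 0")
    return light_mz + n_chemical_acetyl * D3_ACETYL_MASS_SHIFT / charge


def site_stoichiometry(
    pairs: Sequence[FragmentPair], method: str = "pooled"
) -> StoichiometryRecord | None:
    """Acetylation stoichiometry of one site from its fragment pairs.

    ``method="pooled"`` (default) sums light and heavy areas over all
    fragments and fractions before taking the ratio
    ``sum(light) / (sum(light) + sum(heavy))``; ``method="median"``
    instead takes the median of per-pair light/(light+heavy) ratios.
    Pairs with both areas zero are discarded; if no usable pair remains
    the site is skipped (returns None) with a logged warning.
    """
    if method not in ("pooled", "median"):
        raise ValueError(f"unknown method {method!r}")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("site_stoichiometry requires at least one pair")
    keys = {(p.protein_id, p.site) for p in pairs}
    if len(keys) != 1:
        raise ValueError(f"pairs span multiple sites: {sorted(keys)}")
    usable = [p for p in pairs if p.usable]
    if not usable:
        protein_id, site = next(iter(keys))
        logger.warning("site %s K%d skipped: no usable fragment pairs", protein_id, site)
        return None

    if method == "pooled":
        light = sum(p.light_area for p in usable)
        heavy = sum(p.heavy_area for p in usable)
        s = light / (light + heavy)
    else:
        ratios = sorted(p.light_area / (p.light_area + p.heavy_area) for p in usable)
        mid = len(ratios) // 2
        s = ratios[mid] if len(ratios) % 2 else (ratios[mid - 1] + ratios[mid]) / 2.0

    protein_id, site = next(iter(keys))
    return StoichiometryRecord(
        protein_id=protein_id,
        site=site,
        stoichiometry=float(s),
        n_fragments=len({p.fragment_id for p in usable}),
        n_fractions=len({p.fraction for p in usable}),
    )


def aggregate_fractions(
    pairs: Iterable[FragmentPair], method: str = "pooled"
) -> list[StoichiometryRecord]:
    """Per-site stoichiometry over all fractions combined.

    Groups fragment pairs by (protein, site), concatenates the fractions
    of each site and applies :func:`site_stoichiometry`; identical to
    computing each site on the concatenation of its fractions' pairs.
    Sites without usable pairs are skipped (with a logged warning).
    """
    by_site: dict[tuple[str, int], list[FragmentPair]] = {}
    for pair in pairs:
        by_site.setdefault((pair.protein_id, pair.site), []).append(pair)
    records = []
    for key in sorted(by_site):
        record = site_stoichiometry(by_site[key], method=method)
        if record is not None:
            records.append(record)
    return records
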