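"""From peak areas to compositional quantities.

The relative abundance of a peptidoform is its peak area divided by the total
area of all forms of the same peptide in the same sample and replicate, so
each (sample, replicate, region) yields a composition closed to 1.  From the
compositions this module derives:

* **H3 variant proportions** — per replicate, the H3.1 fraction is the total
  H3.1 K27-R40 area over the summed K27-R40 area of both variants; the group
  value is the *median* over replicates and is also formatted as the
  conventional ``a:1`` ratio string (``"3:1"``, ``"1.0:1.0"``).
* **Site-level mark profiles** — marginal abundance of each mutually exclusive
  mark state at one residue, obtained by summing peptidoform fractions over
  all co-modification states (site marginalization).
* **Variant-combined marks** — K27/K36 marks quantified regardless of H3.1 or
  H3.3 origin, as the variant-proportion-weighted average of the two
  variant-resolved profiles.
* **Acetylation-degree profiles** — fraction of forms carrying exactly
  0..k acetyl marks (hyperacetylation readout for H4 G4-R17).

Forms absent from a replicate are *not observed* (excluded from the closure),
not zero-valued; zero handling for statistics lives in :mod:`histoptm.stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regions import (
    MARKS,
    ModificationState,
    ValidationError,
    VARIANT_REGIONS,
    VARIANT_SCOPE,
    format_modstring,
    get_region,
    parse_modstring,
)

logger = logging.getLogger("histoptm")

CLOSURE_TOL = 1e-9


@dataclass(frozen=True)
class FormComposition:
    """Relative abundances of the observed forms of one peptide."""

    sample_group: str
    replicate: int
    region_id: str
    abundances: Mapping[str, float]  # canonical modstring -> fraction

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > CLOSURE_TOL:
            raise ValidationError(
                f"composition for ({self.sample_group}, {self.replicate}, "
                f"{self.region_id}) sums to {total!r}, not 1"
            )
        if any(v < 0 for v in self.abundances.values()):
            raise ValidationError("negative fraction in composition")

    def fraction(self, modstring: str) -> float:
        return self.abundances.get(modstring, 0.0)


@dataclass(frozen=True)
class VariantProportion:
    """H3.1 / H3.3 proportions of one sample group.

    ``p_h31`` is the median over replicates; the per-replicate values are
    retained for box plots and t-tests.  ``ratio_text`` renders the ratio in
    the conventional style: one decimal, integers printed bare ("3:1"), and
    the balanced case printed "1.0:1.0".
    """

    sample_group: str
    p_h31: float
    per_replicate: Mapping[int, float]

    def __post_init__(self) -> None:
        if not 0 < self.p_h31 < 1:
            raise ValidationError(
                f"median H3.1 proportion {self.p_h31} outside (0, 1)"
            )

    @property
    def p_h33(self) -> float:
        return 1.0 - self.p_h31

    @property
    def ratio_text(self) -> str:
        return format_ratio(self.p_h31)


def format_ratio(p_h31: float) -> str:
    """Format a H3.1 fraction as an ``a:1`` ratio string.

    The ratio a = p/(1-p) is rounded to one decimal; whole numbers other than
    1 are printed bare ("3:1", "2:1") and the balanced case as "1.0:1.0".
    Purely presentational — never used in computation.
    """
    a = round(p_h31 / (1.0 - p_h31), 1)
    if a == 1.0:
        return "1.0:1.0"
    if a == int(a):
        return f"{int(a)}:1"
    return f"{a:.1f}:1"


@dataclass(frozen=True)
class SiteMarkProfile:
    """Marginal mark abundances at one residue of one sample/replicate.

    ``variant_scope`` is "H3.1"/"H3.3" for the variant-specific K27-R40
    peptides, "combined" after variant weighting, and "n/a" for peptides
    shared verbatim by both variants (K9-R17, K18-R26, H4).
    """

    sample_group: str
    replicate: int
    site: str
    variant_scope: str
    marks: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.marks.values())
        if abs(total - 1.0) > CLOSURE_TOL:
            raise ValidationError(
                f"site profile {self.site} ({self.sample_group}) sums to {total!r}"
            )


@dataclass(frozen=True)
class AcetylDegreeProfile:
    """Fractions of forms carrying exactly 0..k acetyl marks."""

    sample_group: str
    replicate: int
    region_id: str
    degrees: Mapping[int, float]

    def __post_init__(self) -> None:
        total = sum(self.degrees.values())
        if abs(total - 1.0) > CLOSURE_TOL:
            raise ValidationError(f"acetyl degrees sum to {total!r}, not 1")
        n_lys = get_region(self.region_id).n_lysines
        if any(d < 0 or d > n_lys for d in self.degrees):
            raise ValidationError(
                f"acetyl degree outside 0..{n_lys} for {self.region_id}"
            )


# ---------------------------------------------------------------------------
# relative abundance


def relative_abundance(
    records: pd.DataFrame,
    sample_group: str,
    replicate: int,
    region_id: str,
) -> FormComposition:
    """Close one (sample, replicate, region) slice of peak areas to 1."""
    mask = (
        (records["sample_group"] == sample_group)
        & (records["replicate"] == replicate)
        & (records["region_id"] == region_id)
    )
    sub = records.loc[mask]
    total = sub["peak_area"].sum()
    if sub.empty or total <= 0:
        raise ValidationError(
            f"({sample_group}, {replicate}, {region_id}) has no quantifiable "
            "signal (total area 0)"
        )
    return FormComposition(
        sample_group,
        int(replicate),
        region_id,
        dict(zip(sub["modifications"], sub["peak_area"] / total)),
    )


def compositions(records: pd.DataFrame) -> pd.DataFrame:
    """Relative abundances for every (sample, replicate, region) at once.

    Returns a long DataFrame with columns ``sample_group, replicate,
    region_id, modifications, fraction``.  Slices with zero total area are
    unquantifiable and raise.
    """
    keys = ["sample_group", "replicate", "region_id"]
    totals = records.groupby(keys)["peak_area"].transform("sum")
    if (totals <= 0).any():
        bad = records.loc[totals <= 0, keys].drop_duplicates()
        raise ValidationError(
            "zero total area for:\n" + bad.to_string(index=False)
        )
    out = records[keys + ["modifications"]].copy()
    out["fraction"] = records["peak_area"] / totals
    return out


# ---------------------------------------------------------------------------
# H3 variant proportion


def variant_proportion(records: pd.DataFrame, sample_group: str) -> VariantProportion:
    """H3.1 proportion of one group from the variant-specific K27-R40 peptides.

    Per replicate in which both variants were quantified, the H3.1 proportion
    is total H3.1 area / (total H3.1 + total H3.3 area); the group estimate is
    the median of the per-replicate proportions.
    """
    h31, h33 = VARIANT_REGIONS
    sub = records.loc[
        (records["sample_group"] == sample_group)
        & records["region_id"].isin(VARIANT_REGIONS)
    ]
    totals = sub.groupby(["replicate", "region_id"])["peak_area"].sum().unstack()
    if h31 not in totals.columns or h33 not in totals.columns:
        raise ValidationError(
            f"{sample_group}: both variant peptides must be quantified"
        )
    shared = totals.dropna()
    shared = shared.loc[(shared[h31] > 0) & (shared[h33] > 0)]
    if shared.empty:
        raise ValidationError(
            f"{sample_group}: no replicate quantifies both H3 variant peptides"
        )
    per_rep = (shared[h31] / (shared[h31] + shared[h33])).to_dict()
    return VariantProportion(
        sample_group,
        float(median(per_rep.values())),
        {int(k): float(v) for k, v in per_rep.items()},
    )


def variant_proportions(records: pd.DataFrame) -> dict[str, VariantProportion]:
    """:func:`variant_proportion` for every group that has both variants."""
    out = {}
    for group in pd.unique(records["sample_group"]):
        try:
            out[group] = variant_proportion(records, group)
        except ValidationError as err:
            logger.info("skipping variant proportion for %s: %s", group, err)
    return out


# ---------------------------------------------------------------------------
# site marginalization and variant combination


def marginalize_site(composition: FormComposition, site: str) -> SiteMarkProfile:
    """Collapse co-modification states to the marginal profile of one site."""
    region = get_region(composition.region_id)
    if not region.has_site(site):
        raise ValidationError(
            f"site {site} not in region {composition.region_id}"
        )
    marks = {m: 0.0 for m in MARKS}
    for modstring, frac in composition.abundances.items():
        state = parse_modstring(modstring, region)
        marks[state.mark_at(site)] += frac
    return SiteMarkProfile(
        composition.sample_group,
        composition.replicate,
        site,
        VARIANT_SCOPE[composition.region_id],
        marks,
    )


def site_marks(comps: pd.DataFrame) -> pd.DataFrame:
    """Marginal site-mark profiles for every composition slice.

    Input is the long composition table from :func:`compositions`; output has
    columns ``sample_group, replicate, region_id, variant_scope, site, mark,
    fraction`` with one closed profile per (slice, site).
    """
    frames = []
    for region_id, sub in comps.groupby("region_id", sort=False):
        region = get_region(region_id)
        cache = {
            ms: parse_modstring(ms, region)
            for ms in pd.unique(sub["modifications"])
        }
        for site in region.sites:
            marked = sub.copy()
            marked["mark"] = [cache[ms].mark_at(site) for ms in sub["modifications"]]
            agg = (
                marked.groupby(["sample_group", "replicate", "mark"], as_index=False)[
                    "fraction"
                ].sum()
            )
            agg.insert(2, "region_id", region_id)
            agg.insert(3, "variant_scope", VARIANT_SCOPE[region_id])
            agg.insert(4, "site", site)
            frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def combine_variants(
    profile_h31: SiteMarkProfile,
    profile_h33: SiteMarkProfile,
    vp: VariantProportion,
    weight: float | None = None,
) -> SiteMarkProfile:
    """Variant-weighted site profile: marks quantified regardless of origin.

    The combined abundance of mark m is ``p·h31[m] + (1-p)·h33[m]`` where p is
    the H3.1 proportion — by default the group median in *vp* (the primary
    choice), or an explicit per-replicate *weight*.
    """
    if profile_h31.site != profile_h33.site:
        raise ValidationError(
            f"site mismatch: {profile_h31.site} vs {profile_h33.site}"
        )
    if profile_h31.sample_group != profile_h33.sample_group:
        raise ValidationError(
            f"sample mismatch: {profile_h31.sample_group} vs "
            f"{profile_h33.sample_group}"
        )
    if {profile_h31.variant_scope, profile_h33.variant_scope} != {"H3.1", "H3.3"}:
        raise ValidationError("combine_variants needs one H3.1 and one H3.3 profile")
    if profile_h31.variant_scope == "H3.3":
        profile_h31, profile_h33 = profile_h33, profile_h31
    p = vp.p_h31 if weight is None else float(weight)
    if not 0 <= p <= 1:
        raise ValidationError(f"variant weight {p} outside [0, 1]")
    marks = {
        m: p * profile_h31.marks.get(m, 0.0) + (1 - p) * profile_h33.marks.get(m, 0.0)
        for m in MARKS
    }
    return SiteMarkProfile(
        profile_h31.sample_group,
        profile_h31.replicate,
        profile_h31.site,
        "combined",
        marks,
    )


def combined_site_marks(
    marks: pd.DataFrame,
    vps: Mapping[str, VariantProportion],
    weighting: str = "median",
) -> pd.DataFrame:
    """Combined K27/K36 profiles for every sample and replicate.

    ``weighting="median"`` (primary) weights every replicate by the group's
    median variant proportion; ``"replicate"`` uses each replicate's own
    proportion where available.
    """
    if weighting not in {"median", "replicate"}:
        raise ValidationError(f"unknown weighting {weighting!r}")
    h31 = marks.loc[marks["variant_scope"] == "H3.1"]
    h33 = marks.loc[marks["variant_scope"] == "H3.3"]
    keys = ["sample_group", "replicate", "site", "mark"]
    wide = pd.merge(
        h31[keys + ["fraction"]],
        h33[keys + ["fraction"]],
        on=keys,
        how="inner",
        suffixes=("_h31", "_h33"),
    )
    rows = []
    for (group, rep), sub in wide.groupby(["sample_group", "replicate"]):
        vp = vps.get(group)
        if vp is None:
            logger.info("no variant proportion for %s; skipping combined marks", group)
            continue
        if weighting == "replicate" and int(rep) in vp.per_replicate:
            p = vp.per_replicate[int(rep)]
        else:
            p = vp.p_h31
        frac = p * sub["fraction_h31"] + (1 - p) * sub["fraction_h33"]
        out = sub[keys].copy()
        out["fraction"] = frac.values
        rows.append(out)
    if not rows:
        return pd.DataFrame(columns=keys + ["fraction"])
    combined = pd.concat(rows, ignore_index=True)
    combined.insert(2, "region_id", "H3K27-R40")
    combined.insert(3, "variant_scope", "combined")
    return combined


# ---------------------------------------------------------------------------
# acetylation degree


def acetyl_degree(composition: FormComposition) -> AcetylDegreeProfile:
    """Histogram of acetyl counts: each form contributes to its ac degree."""
    region = get_region(composition.region_id)
    if region.n_lysines < 1:
        raise ValidationError(f"{region.region_id} has no lysines")
    degrees: dict[int, float] = {}
    for modstring, frac in composition.abundances.items():
        k = parse_modstring(modstring, region).n_acetyl
        degrees[k] = degrees.get(k, 0.0) + frac
    return AcetylDegreeProfile(
        composition.sample_group, composition.replicate, composition.region_id,
        degrees,
    )


def acetyl_degrees(comps: pd.DataFrame) -> pd.DataFrame:
    """Acetylation-degree table for every composition slice."""
    frames = []
    for region_id, sub in comps.groupby("region_id", sort=False):
        region = get_region(region_id)
        cache = {
            ms: parse_modstring(ms, region).n_acetyl
            for ms in pd.unique(sub["modifications"])
        }
        tagged = sub.copy()
        tagged["degree"] = [cache[ms] for ms in sub["modifications"]]
        agg = (
            tagged.groupby(["sample_group", "replicate", "degree"], as_index=False)[
                "fraction"
            ].sum()
        )
        agg.insert(2, "region_id", region_id)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
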