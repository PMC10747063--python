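"""Histone peptide regions and per-residue modification states.

Bottom-up histone proteomics quantifies short tryptic (Arg-C-like) peptides
covering the modifiable N-terminal tails of H3 and H4. Four peptides carry
essentially all of the marks discussed here:

* ``H3K9-R17``  (KSTGGKAPR, residues 9-17; sites K9, K14)
* ``H3K18-R26`` (KQLATKAAR, residues 18-26; sites K18, K23)
* ``K27-R40``   — the only peptide that distinguishes the H3 variants:
  H3.1 reads KSAPATGGVKKPHR and H3.3 reads KSAPTTGGVKKPHR (one-residue
  difference at position 31); sites K27, K36
* ``H4G4-R17``  (GKGGKGLGKGGAKR, residues 4-17; sites K5, K8, K12, K16)

Each modifiable lysine carries exactly one state out of
``unmod``/``me1``/``me2``/``me3``/``ac`` (marks are mutually exclusive per
residue). Propionylation introduced during sample preparation is a chemical
label, not a biological mark: propionyl tokens are canonicalized to ``unmod``.

Site labels use protein residue numbering (``K27`` = lysine 27 of H3); no
peptide-internal offsets are exposed anywhere.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger("histoptm")

MARKS: tuple[str, ...] = ("unmod", "me1", "me2", "me3", "ac")

#: Lysines at which trimethylation is routinely reported.  K36me3 is accepted
#: by the data model but flagged with a warning; me3 anywhere else is invalid.
ME3_SITES: frozenset[str] = frozenset({"K9", "K27"})
ME3_FLAGGED_SITES: frozenset[str] = frozenset({"K36"})

#: Tokens treated as the propionyl derivatization label (dropped on parsing).
PROPIONYL_TOKENS: frozenset[str] = frozenset({"pr", "prop", "propionyl"})


class ValidationError(ValueError):
    """A record, modification string, or table violates the data model."""


@dataclass(frozen=True)
class PeptideRegion:
    """One quantified histone peptide with its modifiable sites.

    Parameters
    ----------
    region_id:
        Canonical label, e.g. ``"H3.1K27-R40"``.
    protein:
        Parent histone (``"H3"``, ``"H3.1"``, ``"H3.3"`` or ``"H4"``).
    start, end:
        First and last residue of the peptide in protein coordinates.
    sequence:
        Amino-acid sequence of the unmodified peptide.
    sites:
        Modifiable residues, ordered by position, labelled like ``"K27"``.
    """

    region_id: str
    protein: str
    start: int
    end: int
    sequence: str
    sites: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"{self.region_id}: sequence length {len(self.sequence)} does not "
                f"span residues {self.start}-{self.end}"
            )
        for site in self.sites:
            pos = site_position(site)
            residue = self.sequence[pos - self.start]
            if residue != site[0]:
                raise ValidationError(
                    f"{self.region_id}: residue at position {pos} is {residue}, "
                    f"not {site[0]}"
                )

    @property
    def n_lysines(self) -> int:
        return sum(1 for s in self.sites if s.startswith("K"))

    def has_site(self, site: str) -> bool:
        return site in self.sites


def site_position(site: str) -> int:
    """Protein residue number encoded in a site label (``"K27"`` -> 27)."""
    m = re.fullmatch(r"([A-Z])(\d+)", site)
    if m is None:
        raise ValidationError(f"malformed site label {site!r}")
    return int(m.group(2))


REGIONS: dict[str, PeptideRegion] = {
    r.region_id: r
    for r in (
        PeptideRegion("H3K9-R17", "H3", 9, 17, "KSTGGKAPR", ("K9", "K14")),
        PeptideRegion("H3K18-R26", "H3", 18, 26, "KQLATKAAR", ("K18", "K23")),
        PeptideRegion("H3.1K27-R40", "H3.1", 27, 40, "KSAPATGGVKKPHR", ("K27", "K36")),
        PeptideRegion("H3.3K27-R40", "H3.3", 27, 40, "KSAPTTGGVKKPHR", ("K27", "K36")),
        PeptideRegion("H4G4-R17", "H4", 4, 17, "GKGGKGLGKGGAKR", ("K5", "K8", "K12", "K16")),
    )
}

#: The two variant-specific peptides, quantified jointly for the H3.1:H3.3 ratio.
VARIANT_REGIONS: tuple[str, str] = ("H3.1K27-R40", "H3.3K27-R40")

#: Region id -> variant scope used on site-level mark profiles.
VARIANT_SCOPE: dict[str, str] = {
    "H3.1K27-R40": "H3.1",
    "H3.3K27-R40": "H3.3",
    "H3K9-R17": "n/a",
    "H3K18-R26": "n/a",
    "H4G4-R17": "n/a",
}


def get_region(region_id: str) -> PeptideRegion:
    try:
        return REGIONS[region_id]
    except KeyError:
        raise ValidationError(
            f"unknown region {region_id!r}; known regions: {sorted(REGIONS)}"
        ) from None


@dataclass(frozen=True, order=True)
class ModificationState:
    """Complete assignment of one mark to every modifiable site of a region.

    Stored as a position-ordered tuple of ``(site, mark)`` pairs so states are
    hashable and order-canonical; ``unmod`` sites are part of the assignment
    (mutual exclusivity: each residue carries exactly one state).
    """

    assignments: tuple[tuple[str, str], ...]

    def mark_at(self, site: str) -> str:
        for s, m in self.assignments:
            if s == site:
                return m
        raise ValidationError(f"site {site} not part of this state")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.assignments)

    @property
    def n_acetyl(self) -> int:
        """Number of acetylated sites (the peptide's acetylation degree)."""
        return sum(1 for _, m in self.assignments if m == "ac")

    def to_string(self) -> str:
        """Canonical compact annotation; empty string = fully unmodified."""
        return ";".join(f"{s}:{m}" for s, m in self.assignments if m != "unmod")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string() or "(unmodified)"


def make_state(region: PeptideRegion, marks: Mapping[str, str] | None = None) -> ModificationState:
    """Build a :class:`ModificationState`, defaulting unlisted sites to unmod."""
    marks = dict(marks or {})
    assignments = []
    for site in region.sites:
        mark = marks.pop(site, "unmod")
        _validate_mark(site, mark, region)
        assignments.append((site, mark))
    if marks:
        bad = ", ".join(sorted(marks))
        raise ValidationError(f"site(s) {bad} do not belong to region {region.region_id}")
    return ModificationState(tuple(assignments))


def _validate_mark(site: str, mark: str, region: PeptideRegion) -> None:
    if mark not in MARKS:
        raise ValidationError(
            f"unknown mark {mark!r} at {site} ({region.region_id}); "
            f"expected one of {MARKS}"
        )
    if mark == "me3" and site not in ME3_SITES:
        if site in ME3_FLAGGED_SITES:
            logger.warning("me3 at %s (%s) is unusual; keeping it", site, region.region_id)
        else:
            raise ValidationError(
                f"me3 not permitted at {site} ({region.region_id})"
            )


_TOKEN_SPLIT = re.compile(r"[;\s]+")


def parse_modstring(text: str, region: PeptideRegion) -> ModificationState:
    """Parse a compact ``site:mark`` annotation into a complete state.

    Tokens are separated by semicolons and/or whitespace and may appear in any
    order; unlisted sites are unmodified.  Propionyl tokens (sample-prep
    derivatization, not a biological mark) are dropped with a log notice.

    Raises
    ------
    ValidationError
        For a site not in *region*, a malformed token, or duplicate tokens
        assigning conflicting marks to one site.
    """
    marks: dict[str, str] = {}
    for token in _TOKEN_SPLIT.split(text.strip()):
        if not token:
            continue
        if ":" not in token:
            raise ValidationError(
                f"malformed token {token!r} in {text!r}; expected 'site:mark'"
            )
        site, mark = token.split(":", 1)
        site, mark = site.strip(), mark.strip().lower()
        if mark in PROPIONYL_TOKENS:
            logger.info("dropping propionyl label at %s (%s)", site, region.region_id)
            continue
        if not region.has_site(site):
            raise ValidationError(
                f"site {site!r} does not belong to region {region.region_id}"
            )
        if site in marks and marks[site] != mark:
            raise ValidationError(
                f"conflicting marks {marks[site]!r} and {mark!r} for site {site}"
            )
        marks[site] = mark
    return make_state(region, marks)


def format_modstring(state: ModificationState) -> str:
    """Inverse of :func:`parse_modstring` (canonical compact annotation)."""
    return state.to_string()


def enumerate_states(
    region: PeptideRegion,
    site_marks: Mapping[str, Sequence[str]] | None = None,
) -> Iterator[ModificationState]:
    """Yield every modification state of *region* (optionally restricted).

    ``site_marks`` maps a site to the marks allowed there; unlisted sites get
    the full legal mark set (me3 only where valid).
    """
    site_marks = dict(site_marks or {})
    choices: list[Sequence[str]] = []
    for site in region.sites:
        if site in site_marks:
            choices.append(site_marks[site])
        elif site in ME3_SITES or site in ME3_FLAGGED_SITES:
            choices.append(MARKS)
        else:
            choices.append(tuple(m for m in MARKS if m != "me3"))
    for combo in itertools.product(*choices):
        yield make_state(region, dict(zip(region.sites, combo)))


# -- Skyline-style annotation converter --------------------------------------

#: Monoisotopic mass shifts (Da) seen on propionylated histone peptides.
#: me1 on a free lysine appears together with a propionyl group (+70.042).
_MASS_SHIFT_MARKS: tuple[tuple[float, str], ...] = (
    (42.011, "ac"),
    (14.016, "me1"),
    (28.031, "me2"),
    (42.047, "me3"),
    (56.026, "unmod"),   # propionyl only
    (70.042, "me1"),     # propionyl + monomethyl
    (84.058, "me2"),     # rarely annotated as prop+me2 by some tools
)

_BRACKET = re.compile(r"\[([+-]?\d+(?:\.\d+)?)\]")


def parse_skyline_sequence(modified_sequence: str, region: PeptideRegion,
                           tol: float = 0.02) -> ModificationState:
    """Convert a Skyline-like modified sequence into a modification state.

    Accepts sequences such as ``"KSAPATGGVK[+56.0]K[+42.0]PHR"`` where bracketed
    numbers are mass shifts on the preceding residue.  Propionyl-only shifts
    canonicalize to ``unmod``; unknown shifts raise :class:`ValidationError`.
    """
    marks: dict[str, str] = {}
    pos = region.start - 1
    i = 0
    seq = modified_sequence
    while i < len(seq):
        ch = seq[i]
        if ch == "[":
            m = _BRACKET.match(seq, i)
            if m is None:
                raise ValidationError(f"unbalanced bracket in {modified_sequence!r}")
            shift = float(m.group(1))
            mark = _mark_for_shift(shift, tol)
            if mark is None:
                raise ValidationError(
                    f"unrecognized mass shift {shift:+.3f} in {modified_sequence!r}"
                )
            site = f"{seq[i - 1] if i else '?'}{pos}"
            if mark != "unmod":
                if not region.has_site(site):
                    raise ValidationError(
                        f"mass shift on {site} but {site} is not a site of "
                        f"{region.region_id}"
                    )
                marks[site] = mark
            i = m.end()
        else:
            pos += 1
            if ch != region.sequence[pos - region.start]:
                raise ValidationError(
                    f"sequence mismatch at residue {pos}: {modified_sequence!r} "
                    f"vs region {region.region_id}"
                )
            i += 1
    return make_state(region, marks)


def _mark_for_shift(shift: float, tol: float) -> str | None:
    for ref, mark in _MASS_SHIFT_MARKS:
        if abs(shift - ref) <= tol:
            return mark
    return None
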