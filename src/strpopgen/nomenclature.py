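"""Bracketed STR repeat-structure parsing and CE allele designation.

A repeat structure is written as a sequence of blocks, e.g.
``"AAGA (AAAGA)15"``: a bracketed motif with an integer repeat count, or a
bare DNA run (count 1).  A bracketed motif without a digit also means count
1.  Designation is purely length-based within the analysed region (the ISFG
convention): with motif length ``m`` and total structure length ``L``
(optionally minus a locus-specific offset), the CE label is
``L // m`` full repeats with a ``.(L mod m)`` microvariant suffix.

SE33 is the exception: its published CE nomenclature does not equal total
structure length / 4, and the published off-ladder structures for this locus
are mutually inconsistent under any single length offset, so the default
registry ships SE33 with designation disabled until the offset is calibrated
for the flanking region an assay reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .str_data import AlleleLabel, GenotypeTable

__all__ = [
    "RepeatStructure",
    "LocusNomenclature",
    "RepeatStructureError",
    "parse_repeat_structure",
    "designate_allele",
    "identify_off_ladder",
    "OLResolution",
    "default_registry",
]


class RepeatStructureError(ValueError):
    """Repeat-structure text violates the grammar; carries the offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class RepeatStructure:
    """Ordered (motif, count) blocks parsed from bracketed nomenclature."""

    blocks: tuple[tuple[str, int], ...]
    source_text: str = ""

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError("repeat structure has zero length")

    @property
    def total_length(self) -> int:
        return sum(len(m) * c for m, c in self.blocks)

    def render(self) -> str:
        """Normalized bracketed form; count-1 blocks render as bare runs."""
        parts = []
        for motif, count in self.blocks:
            parts.append(motif if count == 1 else f"({motif}){count}")
        return " ".join(parts)


@dataclass(frozen=True)
class LocusNomenclature:
    """Designation rule for a locus: motif length and optional length offset.

    ``length_offset`` is subtracted from the total structure length before
    conversion to a CE label; ``None`` disables designation for the locus.
    """

    locus: str
    motif_length: int
    length_offset: int | None = 0

    def __post_init__(self) -> None:
        if self.motif_length < 2:
            raise ValueError("motif_length must be >= 2")


_DNA = set("ACGT")


def parse_repeat_structure(text: str) -> RepeatStructure:
    """Parse bracketed repeat-structure text into ordered blocks.

    Grammar (whitespace between blocks optional): a block is either
    ``(MOTIF)`` followed by an optional integer count, or a bare DNA run over
    {A,C,G,T} with count 1.  Unbalanced parentheses, zero counts and illegal
    characters raise :class:`RepeatStructureError` with the offending offset.
    """
    blocks: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            j = text.find(")", i + 1)
            if j == -1:
                raise RepeatStructureError("unbalanced parenthesis", i)
            motif = text[i + 1 : j]
            if not motif or any(c not in _DNA for c in motif):
                raise RepeatStructureError(f"illegal motif {motif!r}", i + 1)
            m = re.match(r"\d+", text[j + 1 :])
            if m:
                count = int(m.group(0))
                if count == 0:
                    raise RepeatStructureError("zero repeat count", j + 1)
                i = j + 1 + m.end()
            else:
                count = 1
                i = j + 1
            blocks.append((motif, count))
        elif ch in _DNA:
            j = i
            while j < n and text[j] in _DNA:
                j += 1
            blocks.append((text[i:j], 1))
            i = j
        else:
            raise RepeatStructureError(f"illegal character {ch!r}", i)
    if not blocks:
        raise RepeatStructureError("empty repeat structure", 0)
    return RepeatStructure(tuple(blocks), source_text=text)


def designate_allele(rs: RepeatStructure, nom: LocusNomenclature) -> AlleleLabel:
    """Length-based CE designation of a parsed repeat structure."""
    if nom.length_offset is None:
        raise ValueError(
            f"designation disabled for locus {nom.locus!r} (uncalibrated offset)"
        )
    L = rs.total_length - nom.length_offset
    if L <= 0:
        raise ValueError(f"effective length {L} <= 0 for {rs.source_text!r}")
    repeats, partial = divmod(L, nom.motif_length)
    return AlleleLabel(repeats, partial)


def default_registry() -> dict[str, LocusNomenclature]:
    """Designation rules for the loci with published off-ladder structures."""
    return {
        "PentaE": LocusNomenclature("PentaE", 5),
        "PentaD": LocusNomenclature("PentaD", 5),
        "D22S1045": LocusNomenclature("D22S1045", 3),
        # SE33 CE nomenclature is not total-length/4; offset left uncalibrated
        "SE33": LocusNomenclature("SE33", 4, length_offset=None),
    }


@dataclass
class OLResolution:
    """Outcome of off-ladder resolution for one (sample, locus) call."""

    sample: str
    locus: str
    status: str  # "identified" | "novel" | "unresolved" | "in_ladder"
    label: AlleleLabel | None = None


def identify_off_ladder(
    g: GenotypeTable,
    structures: dict[str, dict[str, str | RepeatStructure]],
    registry: dict[str, LocusNomenclature] | None = None,
    ladder: dict[str, set[AlleleLabel]] | None = None,
    catalogue: dict[str, set[AlleleLabel]] | None = None,
) -> tuple[GenotypeTable, list[OLResolution]]:
    """Resolve off-ladder (OL) calls from sequenced repeat structures.

    For every OL gene copy with a structure entry, the structure is parsed
    and designated; the call is replaced by the designated label.  Labels
    absent from ``ladder`` are flagged ``"identified"`` (off-ladder but
    designated); labels additionally absent from ``catalogue`` are flagged
    ``"novel"``.  OL calls without a structure stay unresolved.  A structure
    supplied for a non-OL call produces no error (the call wins).
    """
    registry = default_registry() if registry is None else registry
    ladder = ladder or {}
    catalogue = catalogue or {}
    resolutions: list[OLResolution] = []
    new_calls = {s: dict(g.calls[s]) for s in g.samples}

    for sample in g.samples:
        for locus in g.loci:
            call = g.calls[sample][locus]
            if call is None or not any(a.is_off_ladder for a in call):
                continue
            entry = structures.get(sample, {}).get(locus)
            if entry is None:
                resolutions.append(OLResolution(sample, locus, "unresolved"))
                continue
            rs = entry if isinstance(entry, RepeatStructure) else parse_repeat_structure(entry)
            nom = registry.get(locus)
            if nom is None or nom.length_offset is None:
                resolutions.append(OLResolution(sample, locus, "unresolved"))
                continue
            label = designate_allele(rs, nom)
            pair = tuple(label if a.is_off_ladder else a for a in call)
            new_calls[sample][locus] = tuple(sorted(pair))
            if label in ladder.get(locus, set()):
                status = "in_ladder"
            elif label in catalogue.get(locus, set()):
                status = "identified"
            elif catalogue:
                status = "novel"
            else:
                status = "identified"
            resolutions.append(OLResolution(sample, locus, status, label))

    resolved = GenotypeTable(
        list(g.samples), list(g.loci), new_calls, sex=dict(g.sex), subgroup=dict(g.subgroup)
    )
    return resolved, resolutions
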