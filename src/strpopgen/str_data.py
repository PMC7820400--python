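"""Domain types and I/O for STR genotype and allele-frequency data.

Alleles at forensic STR loci are named by capillary-electrophoresis (CE)
convention: the number of full repeat units, with a ``.x`` suffix for x
extra bases (a microvariant), e.g. ``15`` or ``15.3``.  Labels are stored
as exact ``(repeats, partial)`` integer pairs — never floats — so that
microvariant arithmetic is exact and ``9.3`` cannot collide with ``9.30``.

The module also ships two packaged fixtures transcribed from a published
survey of 400 Kuwaiti individuals typed at the 23 autosomal loci of the
PowerPlex Fusion 6C kit: per-locus allele frequencies with forensic summary
statistics, and the repeat structures of the off-ladder alleles observed in
that sample.
"""

from __future__ import annotations

import csv
import functools
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AlleleLabel",
    "GenotypeTable",
    "FrequencyTable",
    "LocusSummary",
    "GenotypeParseError",
    "SchemaError",
    "read_genotype_table",
    "write_genotype_table",
    "frequency_table_from_genotypes",
    "read_frequency_table",
    "write_frequency_table",
    "load_kuwait_frequencies",
    "load_kuwait_reported_stats",
    "load_ol_repeat_structures",
    "KUWAIT_LOCI",
]

#: The 23 autosomal loci of the PowerPlex Fusion 6C kit, in fixture order.
KUWAIT_LOCI = (
    "CSF1PO", "D10S1248", "D12S391", "D13S317", "D16S539", "D18S51",
    "D19S433", "D1S1656", "D21S11", "D22S1045", "D2S1338", "D2S441",
    "D3S1358", "D5S818", "D7S820", "D8S1179", "FGA", "PentaE", "PentaD",
    "TH01", "TPOX", "vWA", "SE33",
)

MISSING = ""  # missing-data sentinel in CSV cells


class GenotypeParseError(ValueError):
    """An allele label or CSV cell could not be parsed."""


class SchemaError(ValueError):
    """A file does not conform to the expected tabular layout."""


_LABEL_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


@dataclass(frozen=True, order=True)
class AlleleLabel:
    """A CE allele designation: full repeats plus a microvariant suffix.

    Ordering is numeric by ``(repeats, partial)``; the off-ladder flag does
    not participate in ordering or equality of resolved labels.
    """

    repeats: int
    partial: int = 0
    is_off_ladder: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise ValueError(f"repeats must be non-negative, got {self.repeats}")
        if not 0 <= self.partial <= 9:
            raise ValueError(f"partial must be a single digit, got {self.partial}")

    @classmethod
    def parse(cls, text: str) -> "AlleleLabel":
        """Parse ``"15"``, ``"15.3"`` or the off-ladder sentinel ``"OL"``."""
        text = text.strip()
        if text.upper() == "OL":
            return cls(0, 0, is_off_ladder=True)
        m = _LABEL_RE.match(text)
        if not m:
            raise GenotypeParseError(f"malformed allele label: {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))

    def __str__(self) -> str:
        if self.is_off_ladder and self.repeats == 0:
            return "OL"
        return f"{self.repeats}.{self.partial}" if self.partial else str(self.repeats)

    def __repr__(self) -> str:  # compact, fixture-diffable
        return f"AlleleLabel({self})"


Call = tuple[AlleleLabel, AlleleLabel]


@dataclass
class GenotypeTable:
    """Diploid allele calls for a panel of samples × loci.

    ``calls[sample][locus]`` is an unordered pair of :class:`AlleleLabel`
    (stored sorted) or ``None`` for missing.  Optional per-sample metadata
    carries sex and a subgroup label.
    """

    samples: list[str]
    loci: list[str]
    calls: dict[str, dict[str, Call | None]]
    sex: dict[str, str] = field(default_factory=dict)
    subgroup: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("GenotypeTable requires at least one sample")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        for s in self.samples:
            row = self.calls.get(s)
            if row is None:
                raise ValueError(f"sample {s!r} has no call row")
            for locus in self.loci:
                call = row.get(locus)
                if call is not None:
                    a, b = call
                    if b < a:
                        row[locus] = (b, a)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def get(self, sample: str, locus: str) -> Call | None:
        return self.calls[sample][locus]

    def called_samples(self, locus: str) -> list[str]:
        """Samples with a non-missing, on-ladder call at ``locus``."""
        out = []
        for s in self.samples:
            call = self.calls[s][locus]
            if call is not None and not (call[0].is_off_ladder or call[1].is_off_ladder):
                out.append(s)
        return out

    def subset(self, samples: Iterable[str]) -> "GenotypeTable":
        samples = list(samples)
        return GenotypeTable(
            samples=samples,
            loci=list(self.loci),
            calls={s: dict(self.calls[s]) for s in samples},
            sex={s: self.sex[s] for s in samples if s in self.sex},
            subgroup={s: self.subgroup[s] for s in samples if s in self.subgroup},
        )


@dataclass
class FrequencyTable:
    """Per-locus allele relative frequencies with sampled-allele counts (2n)."""

    freqs: dict[str, dict[AlleleLabel, float]]
    counts_2n: dict[str, int]

    #: tolerance on per-locus frequency sums (3-decimal printed tables round)
    SUM_TOL = 0.01

    def __post_init__(self) -> None:
        for locus, fmap in self.freqs.items():
            if not fmap:
                raise ValueError(f"locus {locus!r} has an empty frequency map")
            total = sum(fmap.values())
            if not (1 - self.SUM_TOL) <= total <= (1 + self.SUM_TOL):
                raise ValueError(f"locus {locus!r}: frequencies sum to {total:.4f}")
            if any(p <= 0 for p in fmap.values()):
                raise ValueError(f"locus {locus!r}: non-positive frequency")
            n2 = self.counts_2n.get(locus)
            if n2 is None or n2 <= 0 or n2 % 2:
                raise ValueError(f"locus {locus!r}: 2n must be a positive even integer")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def alleles(self, locus: str) -> list[AlleleLabel]:
        return sorted(self.freqs[locus])

    def n_alleles(self, locus: str) -> int:
        return len(self.freqs[locus])


@dataclass(frozen=True)
class LocusSummary:
    """The per-locus forensic statistic bundle of a frequency survey."""

    locus: str
    Ho: float
    He: float
    PIC: float
    PM: float
    DP: float
    PE: float
    TPI: float
    hwe_p: float | None
    n_alleles_observed: int

    def __post_init__(self) -> None:
        for name in ("Ho", "He", "PIC", "PM", "DP", "PE"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.locus}: {name}={v} outside [0,1]")
        if abs(self.DP - (1.0 - self.PM)) > 1e-12:
            raise ValueError(f"{self.locus}: DP must equal 1 - PM")
        if self.TPI < 0.5:
            raise ValueError(f"{self.locus}: TPI={self.TPI} below 0.5")


# ---------------------------------------------------------------------------
# genotype CSV I/O
#
# Layout: header "sample[,sex][,subgroup],<locus>_a1,<locus>_a2,..."; allele
# cells hold CE labels or are empty (missing).  Both cells of a call must be
# present or both empty.

_META_COLS = ("sex", "subgroup")


def _parse_header(header: list[str]) -> tuple[list[str], list[str]]:
    if not header or header[0] != "sample":
        raise SchemaError("first column must be 'sample'")
    meta = []
    i = 1
    while i < len(header) and header[i] in _META_COLS:
        meta.append(header[i])
        i += 1
    allele_cols = header[i:]
    if not allele_cols or len(allele_cols) % 2:
        raise SchemaError(
            f"expected an even number of allele columns, got {len(allele_cols)}"
        )
    loci = []
    for j in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[j], allele_cols[j + 1]
        if not (c1.endswith("_a1") and c2.endswith("_a2") and c1[:-3] == c2[:-3]):
            raise SchemaError(f"allele columns must pair as <locus>_a1,<locus>_a2; got {c1!r},{c2!r}")
        loci.append(c1[:-3])
    return meta, loci


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Read a genotype CSV into a validated :class:`GenotypeTable`.

    Raises
    ------
    SchemaError
        If the header does not follow the ``<locus>_a1,<locus>_a2`` layout.
    GenotypeParseError
        If an allele cell is malformed, naming the row and column.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        meta, loci = _parse_header(header)
        n_meta = len(meta)
        samples: list[str] = []
        calls: dict[str, dict[str, Call | None]] = {}
        sex: dict[str, str] = {}
        subgroup: dict[str, str] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(row):
                continue
            if len(row) != 1 + n_meta + 2 * len(loci):
                raise SchemaError(f"{path}:{lineno}: expected {1 + n_meta + 2 * len(loci)} cells, got {len(row)}")
            sample = row[0]
            samples.append(sample)
            for k, m in enumerate(meta):
                val = row[1 + k]
                if val:
                    (sex if m == "sex" else subgroup)[sample] = val
            srow: dict[str, Call | None] = {}
            for j, locus in enumerate(loci):
                c1 = row[1 + n_meta + 2 * j].strip()
                c2 = row[1 + n_meta + 2 * j + 1].strip()
                if c1 == MISSING and c2 == MISSING:
                    srow[locus] = None
                elif c1 == MISSING or c2 == MISSING:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: half-missing call at locus {locus}"
                    )
                else:
                    try:
                        srow[locus] = (AlleleLabel.parse(c1), AlleleLabel.parse(c2))
                    except GenotypeParseError as e:
                        raise GenotypeParseError(
                            f"{path}:{lineno}: locus {locus}: {e}"
                        ) from None
            calls[sample] = srow
    if not samples:
        raise SchemaError(f"{path}: no sample rows")
    return GenotypeTable(samples, loci, calls, sex=sex, subgroup=subgroup)


def write_genotype_table(g: GenotypeTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        meta = []
        if g.sex:
            meta.append("sex")
        if g.subgroup:
            meta.append("subgroup")
        header = ["sample"] + meta
        for locus in g.loci:
            header += [f"{locus}_a1", f"{locus}_a2"]
        w.writerow(header)
        for s in g.samples:
            row = [s]
            if g.sex:
                row.append(g.sex.get(s, ""))
            if g.subgroup:
                row.append(g.subgroup.get(s, ""))
            for locus in g.loci:
                call = g.calls[s][locus]
                row += ["", ""] if call is None else [str(call[0]), str(call[1])]
            w.writerow(row)


def frequency_table_from_genotypes(g: GenotypeTable) -> FrequencyTable:
    """Tally relative allele frequencies per locus.

    Missing and unresolved off-ladder calls are excluded; each locus's 2n is
    therefore computed per locus.  A locus with no usable calls is an error.
    """
    freqs: dict[str, dict[AlleleLabel, float]] = {}
    counts: dict[str, int] = {}
    for locus in g.loci:
        tally: dict[AlleleLabel, int] = {}
        n2 = 0
        for s in g.called_samples(locus):
            for a in g.calls[s][locus]:
                tally[a] = tally.get(a, 0) + 1
                n2 += 1
        if n2 == 0:
            raise ValueError(f"locus {locus!r} has no non-missing calls")
        freqs[locus] = {a: c / n2 for a, c in sorted(tally.items())}
        counts[locus] = n2
    return FrequencyTable(freqs, counts)


# ---------------------------------------------------------------------------
# frequency-table CSV I/O (loci as columns, alleles as rows)


def write_frequency_table(
    f: FrequencyTable, path: str | Path, decimals: int = 3
) -> None:
    """Write a locus-column/allele-row CSV; absent alleles are blank cells."""
    path = Path(path)
    loci = f.loci
    alleles = sorted({a for locus in loci for a in f.freqs[locus]})
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["allele"] + loci)
        for a in alleles:
            row = [str(a)]
            for locus in loci:
                p = f.freqs[locus].get(a)
                row.append("" if p is None else f"{p:.{decimals}f}")
            w.writerow(row)
        w.writerow(["2n"] + [str(f.counts_2n[locus]) for locus in loci])


def read_frequency_table(path: str | Path, default_2n: int | None = None) -> FrequencyTable:
    """Read a locus-column frequency CSV (the layout of the packaged fixture).

    A trailing ``2n`` row supplies the per-locus sampled-allele counts; if it
    is absent, ``default_2n`` is used for every locus.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(r)]
    if not rows or rows[0][0] != "allele":
        raise SchemaError(f"{path}: first header cell must be 'allele'")
    loci = rows[0][1:]
    freqs: dict[str, dict[AlleleLabel, float]] = {locus: {} for locus in loci}
    counts: dict[str, int] = {}
    for row in rows[1:]:
        if row[0] == "2n":
            counts = {locus: int(v) for locus, v in zip(loci, row[1:])}
            continue
        allele = AlleleLabel.parse(row[0])
        for locus, cell in zip(loci, row[1:]):
            cell = cell.strip()
            # blank, dash and exact zero all mean "allele absent here"
            if cell and cell != "-" and float(cell) > 0.0:
                freqs[locus][allele] = float(cell)
    if not counts:
        if default_2n is None:
            raise SchemaError(f"{path}: no '2n' row and no default_2n given")
        counts = {locus: default_2n for locus in loci}
    return FrequencyTable(freqs, counts)


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return resources.files("strpopgen").joinpath("data", name)


@functools.lru_cache(maxsize=None)
def load_kuwait_frequencies() -> FrequencyTable:
    """Allele frequencies of 400 Kuwaiti individuals at 23 autosomal loci."""
    with resources.as_file(_data_path("kuwait_fusion6c_freqs.csv")) as p:
        return read_frequency_table(p, default_2n=800)


@functools.lru_cache(maxsize=None)
def load_kuwait_reported_stats() -> pd.DataFrame:
    """Published per-locus summary statistics (rows) × loci (columns)."""
    with resources.as_file(_data_path("kuwait_fusion6c_stats.csv")) as p:
        return pd.read_csv(p, index_col=0)


@functools.lru_cache(maxsize=None)
def load_ol_repeat_structures() -> pd.DataFrame:
    """Repeat structures of the off-ladder alleles seen in the Kuwaiti sample."""
    with resources.as_file(_data_path("ol_repeat_structures.csv")) as p:
        return pd.read_csv(p)
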