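"""Core domain types and I/O for HLA class I sequence/frequency analysis.

The coordinate system is the concatenated exon 2 + exon 3 protein alignment
of HLA class I (A, B, C): columns are 1-based, 1..183, with exon 2 spanning
positions 1-90 and exon 3 spanning positions 91-183.  All tables and reports
use this numbering.

Formats handled here: protein / nucleotide FASTA (via Biopython), delimited
frequency and haplotype tables (TSV/CSV via pandas), and a YAML region
configuration.  A documented default region config ships with the package.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Standard amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Single gap / unknown symbol; columns are analyzed over observed non-X symbols.
UNKNOWN = "X"

PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + UNKNOWN)

#: Length of the concatenated exon 2 + exon 3 alignment.
ALIGNMENT_LENGTH = 183

EXON2_POSITIONS = frozenset(range(1, 91))
EXON3_POSITIONS = frozenset(range(91, 184))

NUCLEOTIDES = "ACGT"

#: Default separator between loci in a multi-locus haplotype string,
#: e.g. ``A*01:01~B*08:01``.
HAPLOTYPE_SEPARATOR = "~"


class FormatError(ValueError):
    """A record violates the expected file format."""


class AlignmentError(ValueError):
    """Sequences do not form a consistent alignment."""


class ConfigError(ValueError):
    """A configuration value is invalid."""


def parse_locus(name: str) -> str:
    """Extract the locus from an IMGT/HLA-style allele name.

    The locus is the text before the ``*`` separator, e.g. ``"A"`` for
    ``"A*01:01"``.
    """
    if "*" not in name:
        raise FormatError(f"allele name {name!r} has no '*' locus separator")
    locus = name.split("*", 1)[0]
    if not locus:
        raise FormatError(f"allele name {name!r} has an empty locus")
    return locus


@dataclass(frozen=True)
class Allele:
    """One named, aligned protein sequence."""

    name: str
    sequence: str

    @property
    def locus(self) -> str:
        return parse_locus(self.name)


@dataclass
class AlignedAlleleSet:
    """Named protein sequences over a shared fixed-length alignment.

    Invariants: all sequences have equal length, the alphabet is restricted
    to the 20 amino-acid codes plus ``X`` (gap/unknown), every name parses to
    a locus, and names are unique.
    """

    alleles: list[Allele]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise AlignmentError("empty allele set")
        length = len(self.alleles[0].sequence)
        seen: set[str] = set()
        for allele in self.alleles:
            if len(allele.sequence) != length:
                raise AlignmentError(
                    f"record {allele.name!r} has length {len(allele.sequence)}, "
                    f"expected {length}"
                )
            bad = set(allele.sequence) - PROTEIN_ALPHABET
            if bad:
                raise AlignmentError(
                    f"record {allele.name!r} contains invalid symbols {sorted(bad)}"
                )
            parse_locus(allele.name)
            if allele.name in seen:
                raise AlignmentError(f"duplicate allele name {allele.name!r}")
            seen.add(allele.name)
        self._by_name = {a.name: a for a in self.alleles}

    @property
    def length(self) -> int:
        return len(self.alleles[0].sequence)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.alleles]

    @property
    def loci(self) -> set[str]:
        return {a.locus for a in self.alleles}

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Allele:
        return self._by_name[name]

    def sequence(self, name: str) -> str:
        return self._by_name[name].sequence

    def residue(self, name: str, position: int) -> str:
        """Amino acid of ``name`` at 1-based alignment ``position``."""
        return self._by_name[name].sequence[position - 1]

    def subset(self, names: Iterable[str]) -> "AlignedAlleleSet":
        return AlignedAlleleSet([self._by_name[n] for n in names])

    def restrict_positions(self, positions: Sequence[int]) -> "AlignedAlleleSet":
        """Project every sequence onto the given 1-based positions (sorted)."""
        pos = sorted(positions)
        return AlignedAlleleSet(
            [
                Allele(a.name, "".join(a.sequence[p - 1] for p in pos))
                for a in self.alleles
            ]
        )


@dataclass
class FrequencyTable:
    """Per-population allele frequencies.

    ``entries`` maps ``(population, allele name)`` to a frequency in
    ``(0, 1]``.  Frequencies must be strictly positive because the model
    regresses their base-10 logarithm; per population the frequencies must
    sum to at most 1 (plus a small tolerance).
    """

    entries: dict[tuple[str, str], float]
    populations: list[str] = field(default_factory=list)

    _SUM_TOLERANCE = 1e-6

    def __post_init__(self) -> None:
        pops = sorted({p for p, _ in self.entries})
        if not self.populations:
            self.populations = pops
        for (pop, allele), freq in self.entries.items():
            if not freq > 0:
                raise ValueError(
                    f"frequency of {allele} in {pop} is {freq}; must be > 0"
                )
        for pop in self.populations:
            total = sum(f for (p, _), f in self.entries.items() if p == pop)
            if total > 1 + self._SUM_TOLERANCE:
                raise ValueError(
                    f"frequencies in population {pop} sum to {total:.6g} > 1"
                )

    def alleles(self, population: str | None = None) -> list[str]:
        """Sorted allele names, optionally restricted to one population."""
        if population is None:
            return sorted({a for _, a in self.entries})
        return sorted(a for p, a in self.entries if p == population)

    def frequency(self, population: str, allele: str) -> float:
        return self.entries[(population, allele)]

    def restrict(self, population: str) -> "FrequencyTable":
        return FrequencyTable(
            {k: v for k, v in self.entries.items() if k[0] == population},
            populations=[population],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": p, "allele": a, "frequency": f}
            for (p, a), f in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["population", "allele", "frequency"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FrequencyTable":
        required = {"population", "allele", "frequency"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"frequency table missing columns {sorted(missing)}")
        entries = {
            (str(r.population), str(r.allele)): float(r.frequency)
            for r in frame.itertuples()
        }
        return cls(entries)


@dataclass
class RegionDefinition:
    """Named position sets over the 1..183 alignment, plus excluded alleles.

    ``exon2`` and ``exon3`` partition 1..183.  ``peptide_binding`` and ``bw4``
    may overlap each other and the four structural regions (loop, helices,
    groove, bw4), which must themselves partition 1..183.
    ``excluded_alleles`` lists alleles to drop (e.g. recombination-derived).
    """

    peptide_binding: frozenset[int]
    bw4: frozenset[int]
    loop: frozenset[int]
    helices: frozenset[int]
    groove: frozenset[int]
    exon2: frozenset[int] = EXON2_POSITIONS
    exon3: frozenset[int] = EXON3_POSITIONS
    excluded_alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("peptide_binding", "bw4", "loop", "helices", "groove",
                     "exon2", "exon3"):
            positions = getattr(self, name)
            bad = [p for p in positions if not 1 <= p <= ALIGNMENT_LENGTH]
            if bad:
                raise ConfigError(
                    f"region {name!r} has positions outside 1..{ALIGNMENT_LENGTH}: "
                    f"{sorted(bad)}"
                )
        if self.exon2 & self.exon3:
            raise ConfigError("exon2 and exon3 overlap")
        if self.exon2 | self.exon3 != frozenset(range(1, ALIGNMENT_LENGTH + 1)):
            raise ConfigError("exon2 and exon3 do not cover 1..183")

    def scheme(self, name: str) -> dict[str, frozenset[int]]:
        """Region partition for a comparison scheme.

        Schemes: ``four-region`` (loop / helices / groove / bw4), ``exon``
        (exon2 / exon3), ``pb-vs-npb`` (peptide-binding vs the rest).
        """
        if name == "four-region":
            return {
                "loop": self.loop,
                "helices": self.helices,
                "groove": self.groove,
                "bw4": self.bw4,
            }
        if name == "exon":
            return {"exon2": self.exon2, "exon3": self.exon3}
        if name == "pb-vs-npb":
            pb = self.peptide_binding
            npb = frozenset(range(1, ALIGNMENT_LENGTH + 1)) - pb
            return {"pb": pb, "npb": npb}
        raise ConfigError(f"unknown region scheme {name!r}")


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, expected_length: int | None = None
                   ) -> AlignedAlleleSet:
    """Read a multiple-aligned protein FASTA into an :class:`AlignedAlleleSet`.

    Allele names are the FASTA record ids (IMGT/HLA style, locus before the
    ``*``).  If ``expected_length`` is given every record must have exactly
    that length; otherwise all records must simply agree.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    alleles = []
    for rec in records:
        seq = str(rec.seq).upper()
        if expected_length is not None and len(seq) != expected_length:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(seq)}, "
                f"expected {expected_length}"
            )
        alleles.append(Allele(rec.id, seq))
    return AlignedAlleleSet(alleles)


def write_alignment(alleles: AlignedAlleleSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description="")
        for a in alleles.alleles
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Frequency and haplotype tables
# ---------------------------------------------------------------------------

def read_frequency_table(path: str | Path, sep: str = "\t") -> FrequencyTable:
    """Read a delimited table with columns ``population``, ``allele``,
    ``frequency``."""
    frame = pd.read_csv(Path(path), sep=sep)
    return FrequencyTable.from_frame(frame)


def write_frequency_table(table: FrequencyTable, path: str | Path,
                          sep: str = "\t") -> None:
    table.to_frame().to_csv(Path(path), sep=sep, index=False)


def read_haplotype_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table with columns ``population``, ``haplotype``,
    ``frequency`` (haplotypes are ``~``-joined allele names)."""
    frame = pd.read_csv(Path(path), sep=sep)
    required = {"population", "haplotype", "frequency"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"haplotype table missing columns {sorted(missing)}")
    return frame


def marginalize_haplotypes(haplotypes: pd.DataFrame, locus: str,
                           separator: str = HAPLOTYPE_SEPARATOR
                           ) -> FrequencyTable:
    """Derive single-locus allele frequencies as marginal sums of multi-locus
    haplotype frequencies.

    Each haplotype string is a ``separator``-joined list of allele names; the
    frequency of allele *a* in population *p* is the sum of the frequencies
    of all of *p*'s haplotypes that carry *a* at the requested locus.  Total
    mass per population is conserved exactly.
    """
    entries: dict[tuple[str, str], float] = {}
    for row in haplotypes.itertuples():
        parts = str(row.haplotype).split(separator)
        matches = [p for p in parts if parse_locus(p) == locus]
        if not matches:
            raise FormatError(
                f"haplotype {row.haplotype!r} has no allele at locus {locus!r}"
            )
        if len(matches) > 1:
            raise FormatError(
                f"haplotype {row.haplotype!r} has multiple {locus!r} alleles"
            )
        key = (str(row.population), matches[0])
        entries[key] = entries.get(key, 0.0) + float(row.frequency)
    return FrequencyTable(entries)


# ---------------------------------------------------------------------------
# Region configuration
# ---------------------------------------------------------------------------

def _parse_positions(spec: object) -> frozenset[int]:
    """Parse a YAML position spec: a list of ints and/or 'a-b' range strings."""
    if spec is None:
        return frozenset()
    positions: set[int] = set()
    items = spec if isinstance(spec, list) else [spec]
    for item in items:
        if isinstance(item, int):
            positions.add(item)
        elif isinstance(item, str) and "-" in item:
            lo, hi = item.split("-", 1)
            positions.update(range(int(lo), int(hi) + 1))
        else:
            raise ConfigError(f"cannot parse position spec {item!r}")
    return frozenset(positions)


def load_regions(path: str | Path | None = None) -> RegionDefinition:
    """Load a region configuration, or the package default if ``path`` is None.

    The YAML file maps region names (``peptide_binding``, ``bw4``, ``loop``,
    ``helices``, ``groove``, optionally ``exon2``/``exon3``) to position
    lists, where entries may be integers or ``"a-b"`` range strings, plus an
    optional ``excluded_alleles`` name list.
    """
    if path is None:
        ref = importlib.resources.files("hlaselect.data") / "regions_default.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("region config must be a mapping")
    kwargs: dict = {}
    for name in ("peptide_binding", "bw4", "loop", "helices", "groove"):
        if name not in raw:
            raise ConfigError(f"region config missing {name!r}")
        kwargs[name] = _parse_positions(raw[name])
    for name in ("exon2", "exon3"):
        if name in raw:
            kwargs[name] = _parse_positions(raw[name])
    kwargs["excluded_alleles"] = tuple(raw.get("excluded_alleles") or ())
    return RegionDefinition(**kwargs)


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

AMBIGUOUS_OK = frozenset("ACGTRYSWKMBDHVN-")


@dataclass
class CodonAlignment:
    """Aligned in-frame nucleotide sequences.

    Sequence length must be divisible by 3.  Sequences containing symbols
    outside ``{A, C, G, T}`` are flagged (``ambiguous_names``) so callers can
    exclude them from codon statistics.
    """

    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("empty codon alignment")
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names and sequences differ in count")
        length = len(self.sequences[0])
        if length % 3 != 0:
            raise AlignmentError(f"alignment length {length} not divisible by 3")
        for name, seq in zip(self.names, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"record {name!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - AMBIGUOUS_OK
            if bad:
                raise AlignmentError(
                    f"record {name!r} contains invalid symbols {sorted(bad)}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    @property
    def ambiguous_names(self) -> list[str]:
        """Names of sequences containing non-ACGT symbols."""
        plain = frozenset(NUCLEOTIDES)
        return [
            n for n, s in zip(self.names, self.sequences) if set(s) - plain
        ]

    def drop_ambiguous(self) -> "CodonAlignment":
        """Return the alignment without sequences containing non-ACGT codes."""
        bad = set(self.ambiguous_names)
        if bad:
            logger.info("dropping %d sequences with ambiguous codes", len(bad))
        names, seqs = zip(
            *[(n, s) for n, s in zip(self.names, self.sequences) if n not in bad]
        )
        return CodonAlignment(list(names), list(seqs))

    def codon(self, seq_index: int, codon_index: int) -> str:
        """Codon at 0-based ``codon_index`` of sequence ``seq_index``."""
        return self.sequences[seq_index][3 * codon_index: 3 * codon_index + 3]


def read_codon_alignment(path: str | Path) -> CodonAlignment:
    records = list(SeqIO.parse(str(Path(path)), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return CodonAlignment(
        [r.id for r in records], [str(r.seq).upper() for r in records]
    )


def write_codon_alignment(alignment: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=n, description="")
        for n, s in zip(alignment.names, alignment.sequences)
    ]
    SeqIO.write(records, str(Path(path)), "fasta")
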