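"""Data model and I/O for multilocus microsatellite genotypes.

Genotypes are diploid microsatellite calls: an unordered pair of allele
labels, where a label is the integer PCR fragment length in base pairs.
Homozygotes are stored as the same label twice so gene-copy counting is
uniform; a missing call is simply absent (``get`` returns ``None``), never
encoded as 0, to avoid collision with the GenePop ``000`` missing code.

The default locus panel is the nine-marker equine MHC microsatellite panel
(three class I and six class II loci on chromosome 20), amplified in three
multiplexes.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import (
    EncodingError,
    ParseError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "LocusDef",
    "LocusPanel",
    "GenotypeTable",
    "PairRecord",
    "AlleleFrequencyTable",
    "default_panel",
    "read_genotypes",
    "write_genotypes_csv",
    "write_genepop",
    "allele_frequencies",
    "check_trio_consistency",
    "read_pairs",
    "write_pairs",
]


@dataclass(frozen=True)
class LocusDef:
    """One microsatellite locus: name, MHC class, amplicon size range, multiplex."""

    name: str
    mhc_class: str  # "I" or "II"
    size_range: tuple[int, int]
    multiplex: int

    def __post_init__(self) -> None:
        if self.mhc_class not in ("I", "II"):
            raise ValidationError(
                f"locus {self.name}: mhc_class must be 'I' or 'II', got {self.mhc_class!r}"
            )
        lo, hi = self.size_range
        if lo > hi:
            raise ValidationError(f"locus {self.name}: empty size range {self.size_range}")


class LocusPanel:
    """Ordered collection of loci with unique names and MHC class labels."""

    def __init__(self, loci: Sequence[LocusDef]):
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValidationError("locus names in a panel must be unique")
        self._loci = tuple(loci)
        self._by_name = {l.name: l for l in loci}

    @property
    def names(self) -> list[str]:
        return [l.name for l in self._loci]

    def class_loci(self, mhc_class: str) -> list[str]:
        """Names of the loci in one MHC class, in panel order."""
        return [l.name for l in self._loci if l.mhc_class == mhc_class]

    def __iter__(self) -> Iterator[LocusDef]:
        return iter(self._loci)

    def __len__(self) -> int:
        return len(self._loci)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> LocusDef:
        return self._by_name[name]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": l.name,
                "mhc_class": l.mhc_class,
                "size_range": list(l.size_range),
                "multiplex": l.multiplex,
            }
            for l in self._loci
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LocusPanel":
        payload = json.loads(Path(path).read_text())
        return cls(
            [
                LocusDef(
                    name=e["name"],
                    mhc_class=e["mhc_class"],
                    size_range=tuple(e["size_range"]),
                    multiplex=int(e["multiplex"]),
                )
                for e in payload
            ]
        )


#: The nine-locus equine MHC microsatellite panel, in genomic/multiplex order.
DEFAULT_PANEL = LocusPanel(
    [
        LocusDef("ABGe9030", "II", (193, 209), 1),
        LocusDef("TKY3324", "II", (239, 261), 1),
        LocusDef("COR110", "I", (197, 214), 1),
        LocusDef("COR112", "II", (230, 260), 2),
        LocusDef("TAMU30593", "I", (329, 345), 2),
        LocusDef("COR113", "II", (248, 272), 3),
        LocusDef("COR114", "II", (225, 245), 3),
        LocusDef("UM011", "II", (158, 173), 3),
        LocusDef("UMN-JH38", "I", (149, 157), 3),
    ]
)


def default_panel() -> LocusPanel:
    """Return the default nine-locus MHC panel (3 class I, 6 class II)."""
    return DEFAULT_PANEL


Call = tuple[int, int]


class GenotypeTable:
    """Individuals x loci table of diploid allele calls with missing-data support.

    ``get(individual, locus)`` returns a sorted ``(a, b)`` tuple of integer
    allele labels, or ``None`` when the call is missing.
    """

    def __init__(self, loci: Sequence[str]):
        self.loci = list(loci)
        self._locus_set = set(self.loci)
        self._individuals: list[str] = []
        self._ind_set: set[str] = set()
        self._calls: dict[tuple[str, str], Call] = {}

    @property
    def individuals(self) -> list[str]:
        return list(self._individuals)

    def __contains__(self, individual: str) -> bool:
        return individual in self._ind_set

    def __len__(self) -> int:
        return len(self._individuals)

    def add_individual(self, individual: str) -> None:
        if individual in self._ind_set:
            raise ValidationError(f"duplicate individual id {individual!r}")
        self._individuals.append(individual)
        self._ind_set.add(individual)

    def set_call(self, individual: str, locus: str, a: int, b: int) -> None:
        if individual not in self._ind_set:
            self.add_individual(individual)
        if locus not in self._locus_set:
            raise SchemaError(f"locus {locus!r} not in table loci")
        a, b = int(a), int(b)
        if a <= 0 or b <= 0:
            raise ValidationError(
                f"{individual}/{locus}: allele labels must be positive integers, got ({a}, {b})"
            )
        self._calls[(individual, locus)] = (a, b) if a <= b else (b, a)

    def get(self, individual: str, locus: str) -> Call | None:
        return self._calls.get((individual, locus))

    def row(self, individual: str) -> dict[str, Call]:
        """Non-missing calls of one individual as a locus -> call mapping."""
        if individual not in self._ind_set:
            raise ValidationError(f"unknown individual {individual!r}")
        out = {}
        for locus in self.loci:
            call = self._calls.get((individual, locus))
            if call is not None:
                out[locus] = call
        return out

    def subset(self, individuals: Iterable[str]) -> "GenotypeTable":
        sub = GenotypeTable(self.loci)
        for ind in individuals:
            if ind not in self._ind_set:
                raise ValidationError(f"unknown individual {ind!r}")
            sub.add_individual(ind)
            for locus in self.loci:
                call = self._calls.get((ind, locus))
                if call is not None:
                    sub._calls[(ind, locus)] = call
        return sub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.loci == other.loci
            and self._individuals == other._individuals
            and self._calls == other._calls
        )


@dataclass(frozen=True)
class PairRecord:
    """One mare-foal pair with its retained-fetal-membranes (RFM) status."""

    mare_id: str
    foal_id: str
    rfm: bool

    def __post_init__(self) -> None:
        if self.mare_id == self.foal_id:
            raise ValidationError(f"pair with identical mare and foal id {self.mare_id!r}")

    @property
    def group(self) -> str:
        return "RFM" if self.rfm else "control"


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies plus the number of gene copies counted."""

    freqs: dict[str, dict[int, float]]
    sample_size: dict[str, int]

    def __post_init__(self) -> None:
        for locus, f in self.freqs.items():
            total = sum(f.values())
            if abs(total - 1.0) > 1e-12:
                raise ValidationError(f"locus {locus}: frequencies sum to {total}, not 1")

    def __getitem__(self, locus: str) -> dict[int, float]:
        return self.freqs[locus]

    def __contains__(self, locus: str) -> bool:
        return locus in self.freqs

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)


# ---------------------------------------------------------------------------
# CSV dialect: one row per individual, columns id, <locus>_1, <locus>_2 x 9.


def _parse_allele(text: str, line_no: int, path: str) -> int | None:
    text = text.strip()
    if text == "" or text.upper() in ("NA", "NAN", "."):
        return None
    try:
        value = int(text)
    except ValueError as exc:
        raise ParseError(f"{path}: line {line_no}: cannot parse allele {text!r}") from exc
    if value <= 0:
        raise ParseError(f"{path}: line {line_no}: allele label must be positive, got {value}")
    return value


def _read_genotypes_csv(path: str | Path, panel: LocusPanel) -> GenotypeTable:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if not header or header[0].lower() != "id":
            raise SchemaError(f"{path}: first column must be 'id', got {header[:1]}")
        loci_cols: list[tuple[str, int]] = []  # (locus, 1|2) per column
        for col in header[1:]:
            if "_" not in col:
                raise SchemaError(f"{path}: column {col!r} is not of the form <locus>_1/<locus>_2")
            locus, _, suffix = col.rpartition("_")
            if suffix not in ("1", "2"):
                raise SchemaError(f"{path}: column {col!r} must end in _1 or _2")
            if locus not in panel:
                raise SchemaError(f"{path}: locus {locus!r} not in panel")
            loci_cols.append((locus, int(suffix)))
        seen = {}
        for locus, suffix in loci_cols:
            seen.setdefault(locus, set()).add(suffix)
        for locus, suffixes in seen.items():
            if suffixes != {1, 2}:
                raise SchemaError(f"{path}: locus {locus!r} needs both _1 and _2 columns")
        loci = list(seen)

        table = GenotypeTable(loci)
        for line_no, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {line_no}: expected {len(header)} fields, got {len(row)}"
                )
            ind = row[0].strip()
            if not ind:
                raise ParseError(f"{path}: line {line_no}: empty individual id")
            table.add_individual(ind)
            values: dict[tuple[str, int], int | None] = {}
            for (locus, suffix), cell in zip(loci_cols, row[1:]):
                values[(locus, suffix)] = _parse_allele(cell, line_no, str(path))
            for locus in loci:
                a, b = values[(locus, 1)], values[(locus, 2)]
                if (a is None) != (b is None):
                    raise ValidationError(
                        f"{path}: line {line_no}: single-allele call at locus {locus}"
                    )
                if a is not None and b is not None:
                    table.set_call(ind, locus, a, b)
    return table


def write_genotypes_csv(table: GenotypeTable, path: str | Path) -> None:
    """Write the two-columns-per-locus CSV dialect; missing calls as empty cells."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["id"]
        for locus in table.loci:
            header += [f"{locus}_1", f"{locus}_2"]
        writer.writerow(header)
        for ind in table.individuals:
            row: list[str] = [ind]
            for locus in table.loci:
                call = table.get(ind, locus)
                row += ["", ""] if call is None else [str(call[0]), str(call[1])]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# GenePop dialect with 3-digit allele codes and a sidecar code <-> bp map.

_GENEPOP_MISSING = "000000"


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".alleles.tsv")


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "placmatch export") -> None:
    """Write a GenePop-format file plus a TSV sidecar mapping codes to bp lengths.

    Allele codes are 3-digit, assigned per locus by ascending fragment length
    (bp lengths themselves exceed three digits, so direct encoding is not
    possible). ``read_genotypes(format="genepop")`` inverts this exactly.
    """
    if len(table) == 0:
        raise ValidationError("no individuals to write")
    path = Path(path)
    code_map: dict[str, dict[int, int]] = {}
    for locus in table.loci:
        alleles = sorted(
            {a for ind in table.individuals for a in (table.get(ind, locus) or ())}
        )
        if len(alleles) > 999:
            raise EncodingError(f"locus {locus}: {len(alleles)} alleles exceed 3-digit coding")
        code_map[locus] = {bp: i + 1 for i, bp in enumerate(alleles)}

    with path.open("w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for ind in table.individuals:
            fields = []
            for locus in table.loci:
                call = table.get(ind, locus)
                if call is None:
                    fields.append(_GENEPOP_MISSING)
                else:
                    a, b = call
                    fields.append(f"{code_map[locus][a]:03d}{code_map[locus][b]:03d}")
            fh.write(f"{ind} ,  " + " ".join(fields) + "\n")

    with _sidecar_path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["locus", "code", "bp"])
        for locus in table.loci:
            for bp, code in code_map[locus].items():
                writer.writerow([locus, f"{code:03d}", bp])


def _read_allele_map(path: Path) -> dict[str, dict[int, int]]:
    decode: dict[str, dict[int, int]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            decode.setdefault(row["locus"], {})[int(row["code"])] = int(row["bp"])
    return decode


def _read_genotypes_genepop(path: str | Path, panel: LocusPanel) -> GenotypeTable:
    path = Path(path)
    sidecar = _sidecar_path(path)
    decode = _read_allele_map(sidecar) if sidecar.exists() else None
    if decode is None:
        warnings.warn(
            f"{path}: no sidecar allele map found; using raw 3-digit codes as allele labels",
            stacklevel=2,
        )
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GenePop file")
    loci: list[str] = []
    pop_line = None
    for i, line in enumerate(lines[1:], start=2):
        if line.strip().lower() == "pop":
            pop_line = i
            break
        for name in line.split(","):
            name = name.strip()
            if name:
                loci.append(name)
    if pop_line is None:
        raise ParseError(f"{path}: no 'Pop' line found")
    for locus in loci:
        if locus not in panel:
            raise SchemaError(f"{path}: locus {locus!r} not in panel")

    table = GenotypeTable(loci)
    for line_no, line in enumerate(lines[pop_line:], start=pop_line + 1):
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            continue  # single population expected; further Pop blocks are merged
        if "," not in line:
            raise ParseError(f"{path}: line {line_no}: missing ',' separator")
        ind, _, rest = line.partition(",")
        ind = ind.strip()
        codes = rest.split()
        if len(codes) != len(loci):
            raise ParseError(
                f"{path}: line {line_no}: expected {len(loci)} genotypes, got {len(codes)}"
            )
        table.add_individual(ind)
        for locus, code in zip(loci, codes):
            if len(code) not in (4, 6) or not code.isdigit():
                raise ParseError(f"{path}: line {line_no}: bad genotype code {code!r}")
            half = len(code) // 2
            c1, c2 = int(code[:half]), int(code[half:])
            if c1 == 0 and c2 == 0:
                continue
            if c1 == 0 or c2 == 0:
                raise ValidationError(f"{path}: line {line_no}: single-allele call at {locus}")
            if decode is not None:
                try:
                    a, b = decode[locus][c1], decode[locus][c2]
                except KeyError as exc:
                    raise ParseError(
                        f"{path}: line {line_no}: code {exc} not in sidecar map for {locus}"
                    ) from None
            else:
                a, b = c1, c2
            table.set_call(ind, locus, a, b)
    return table


def read_genotypes(
    path: str | Path, format: str = "csv", panel: LocusPanel | None = None
) -> GenotypeTable:
    """Read a genotype table from ``csv`` or ``genepop`` format, validated against a panel."""
    panel = panel or DEFAULT_PANEL
    if format == "csv":
        return _read_genotypes_csv(path, panel)
    if format == "genepop":
        return _read_genotypes_genepop(path, panel)
    raise ValidationError(f"unknown format {format!r} (expected 'csv' or 'genepop')")


# ---------------------------------------------------------------------------


def allele_frequencies(
    table: GenotypeTable,
    individuals: Sequence[str] | None = None,
    loci: Sequence[str] | None = None,
) -> AlleleFrequencyTable:
    """Empirical allele frequencies per locus, counting non-missing gene copies.

    Missing calls are excluded locus-wise; a locus with no genotyped
    individual in the chosen subset is dropped with a warning.
    """
    inds = list(individuals) if individuals is not None else table.individuals
    loci = list(loci) if loci is not None else table.loci
    freqs: dict[str, dict[int, float]] = {}
    sizes: dict[str, int] = {}
    for locus in loci:
        counts: dict[int, int] = {}
        for ind in inds:
            call = table.get(ind, locus)
            if call is None:
                continue
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"locus {locus}: all calls missing; excluded from frequencies",
                          stacklevel=2)
            continue
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
        sizes[locus] = total
    return AlleleFrequencyTable(freqs=freqs, sample_size=sizes)


def check_trio_consistency(
    foal_id: str, dam_id: str, sire_id: str, table: GenotypeTable
) -> dict[str, bool | None]:
    """Mendelian consistency of a foal/dam/sire trio, locus by locus.

    A locus is consistent iff the foal's two alleles can be split into one
    allele present in the dam and one present in the sire. Loci with a
    missing call in any trio member are reported as ``None`` (untestable).
    Inconsistent loci are candidate null-allele or typing-error signals.
    """
    for ind in (foal_id, dam_id, sire_id):
        if ind not in table:
            raise ValidationError(f"trio member {ind!r} not genotyped")
    report: dict[str, bool | None] = {}
    for locus in table.loci:
        foal = table.get(foal_id, locus)
        dam = table.get(dam_id, locus)
        sire = table.get(sire_id, locus)
        if foal is None or dam is None or sire is None:
            report[locus] = None
            continue
        a, b = foal
        dam_set, sire_set = set(dam), set(sire)
        report[locus] = (a in dam_set and b in sire_set) or (b in dam_set and a in sire_set)
    return report


# ---------------------------------------------------------------------------
# Pair metadata.

_TRUE = {"1", "true", "yes", "rfm"}
_FALSE = {"0", "false", "no", "control"}


def read_pairs(path: str | Path) -> list[PairRecord]:
    """Read pair metadata CSV with columns mare_id, foal_id, rfm."""
    path = Path(path)
    pairs: list[PairRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"mare_id", "foal_id", "rfm"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(f"{path}: expected columns {sorted(required)}")
        for line_no, row in enumerate(reader, start=2):
            flag = row["rfm"].strip().lower()
            if flag in _TRUE:
                rfm = True
            elif flag in _FALSE:
                rfm = False
            else:
                raise ParseError(f"{path}: line {line_no}: cannot parse rfm value {row['rfm']!r}")
            pairs.append(PairRecord(row["mare_id"].strip(), row["foal_id"].strip(), rfm))
    return pairs


def write_pairs(pairs: Sequence[PairRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mare_id", "foal_id", "rfm"])
        for p in pairs:
            writer.writerow([p.mare_id, p.foal_id, int(p.rfm)])


def validate_pairs(pairs: Sequence[PairRecord], table: GenotypeTable) -> None:
    """Check that every pair member is present in the genotype table."""
    if not pairs:
        raise ValidationError("no mare-foal pairs provided")
    for p in pairs:
        for ind in (p.mare_id, p.foal_id):
            if ind not in table:
                raise ValidationError(f"pair member {ind!r} missing from genotype table")
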