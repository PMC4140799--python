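"""Microsatellite genotype data model and file I/O.

Workers of social Hymenoptera are diploid; males are haploid, so a male
contributes a single allele per locus.  Genotypes are stored as integer
allele (fragment) lengths, the way microsatellites are scored.  Two
tabular formats are supported: a simple CSV/TSV worker-genotype table
(one row per worker, one ``a/b`` column per locus) and GENEPOP text for
parent genotypes, where haploid males are conventionally written as
homozygous diploids and queens are duplicated so that allele counts in
downstream diploid software weight each parent's genome equally.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Locus",
    "ColonySample",
    "ParentSet",
    "AlleleFrequencyTable",
    "GenotypeParseError",
    "GenepopEncodingError",
    "read_genotype_table",
    "write_genotype_table",
    "write_genepop",
    "read_genepop",
    "allele_frequencies",
    "write_frequency_table",
]

# A diploid genotype is a tuple over the locus panel; each entry is an
# unordered allele pair stored sorted, or None when untyped.
DiploidGenotype = tuple[Optional[tuple[int, int]], ...]
# A haplotype holds one allele per locus, or None when unknown.
Haplotype = tuple[Optional[int], ...]


class GenotypeParseError(ValueError):
    """Malformed genotype table (bad allele token, inconsistent panel...)."""


class GenepopEncodingError(ValueError):
    """Allele not representable in the chosen GENEPOP digit coding."""


@dataclass(frozen=True)
class Locus:
    """One microsatellite locus in a panel.

    ``alleles`` records the fragment lengths observed so far; it is
    informational and updated by readers, not enforced on genotypes.
    """

    name: str
    alleles: frozenset[int] = frozenset()
    missing_code: str = "0"

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alleles):
            raise ValueError(f"locus {self.name}: allele lengths must be positive")


def _check_panel(panel: Sequence[Locus]) -> None:
    names = [l.name for l in panel]
    if len(set(names)) != len(names):
        raise ValueError("locus names must be unique within a panel")


def sort_pair(a: int, b: int) -> tuple[int, int]:
    """Canonical (unordered) allele pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ColonySample:
    """Worker diploid multilocus genotypes for one colony."""

    colony_id: str
    species_id: str
    location: str
    panel: list[Locus]
    workers: list[DiploidGenotype]
    worker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_panel(self.panel)
        for w in self.workers:
            if len(w) != len(self.panel):
                raise ValueError(
                    f"colony {self.colony_id}: worker genotype length "
                    f"{len(w)} != panel size {len(self.panel)}"
                )
        if not self.worker_ids:
            self.worker_ids = [f"{self.colony_id}_w{i}" for i in range(len(self.workers))]

    @property
    def n_workers(self) -> int:
        return len(self.workers)

    def n_typed_loci(self, worker_index: int) -> int:
        return sum(g is not None for g in self.workers[worker_index])


@dataclass
class ParentSet:
    """Deduced queen and mate genotypes for one colony.

    The queen is diploid; each mate is a haploid patriline genotype.
    """

    colony_id: str
    panel: list[Locus]
    queen: DiploidGenotype
    males: list[Haplotype]

    def __post_init__(self) -> None:
        _check_panel(self.panel)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele relative frequencies with the underlying counts.

    Loci are keyed by name; per locus, ``counts`` maps allele -> gene-copy
    count and ``freqs`` maps allele -> relative frequency summing to 1.
    """

    loci: list[str]
    counts: dict[str, dict[int, float]]
    freqs: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for locus in self.loci:
            total = sum(self.freqs[locus].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"locus {locus}: frequencies sum to {total}, not 1")
            if any(not (0.0 <= f <= 1.0) for f in self.freqs[locus].values()):
                raise ValueError(f"locus {locus}: frequency outside [0, 1]")

    def homozygosity(self, locus: str) -> float:
        """Sum of squared allele frequencies (match probability of two
        random gene copies)."""
        return sum(f * f for f in self.freqs[locus].values())

    def subset(self, loci: Iterable[str]) -> "AlleleFrequencyTable":
        keep = [l for l in self.loci if l in set(loci)]
        return AlleleFrequencyTable(
            loci=keep,
            counts={l: dict(self.counts[l]) for l in keep},
            freqs={l: dict(self.freqs[l]) for l in keep},
        )


# ---------------------------------------------------------------------------
# Worker genotype tables (CSV/TSV)
# ---------------------------------------------------------------------------

_META_COLUMNS = ("colony", "species", "location", "worker")


def _parse_allele_pair(token: str, missing: str, row: int, locus: str) -> Optional[tuple[int, int]]:
    token = token.strip()
    if token in ("", missing, f"{missing}/{missing}"):
        return None
    parts = token.split("/")
    if len(parts) != 2:
        raise GenotypeParseError(
            f"row {row}, locus {locus}: expected 'a/b' allele token, got {token!r}"
        )
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise GenotypeParseError(
            f"row {row}, locus {locus}: non-integer allele in {token!r}"
        ) from exc
    if a <= 0 or b <= 0:
        if a == 0 and b == 0:
            return None
        raise GenotypeParseError(
            f"row {row}, locus {locus}: allele lengths must be positive in {token!r}"
        )
    return sort_pair(a, b)


def read_genotype_table(
    path, dialect: str = "csv", missing: str = "0/0"
) -> list[ColonySample]:
    """Read a worker genotype table into colonies.

    The header row names the loci after the metadata columns
    ``colony, species, location, worker`` (``location``/``worker``
    optional).  Alleles are encoded ``a/b``; the missing sentinel
    defaults to ``0/0``.  Rows are grouped by colony in order of first
    appearance; worker order within a colony is preserved.
    """
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader, None)
        if header is None:
            raise GenotypeParseError(f"{path}: empty file")
        header = [h.strip() for h in header]
        meta_cols = [h for h in header if h.lower() in _META_COLUMNS]
        locus_names = [h for h in header if h.lower() not in _META_COLUMNS]
        if "colony" not in [m.lower() for m in meta_cols] or not locus_names:
            raise GenotypeParseError(
                f"{path}: header must contain a 'colony' column and locus columns"
            )
        col_index = {h.lower(): i for i, h in enumerate(header)}
        missing_allele = missing.split("/")[0]
        panel = [Locus(name, missing_code=missing_allele) for name in locus_names]
        locus_pos = [header.index(name) for name in locus_names]

        order: list[str] = []
        rows: dict[str, dict] = {}
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise GenotypeParseError(
                    f"{path}: row {rownum} has {len(row)} fields, header has {len(header)}"
                )
            colony = row[col_index["colony"]].strip()
            species = row[col_index["species"]].strip() if "species" in col_index else ""
            location = row[col_index["location"]].strip() if "location" in col_index else ""
            worker = row[col_index["worker"]].strip() if "worker" in col_index else ""
            geno = tuple(
                _parse_allele_pair(row[pos], missing, rownum, name)
                for pos, name in zip(locus_pos, locus_names)
            )
            if colony not in rows:
                order.append(colony)
                rows[colony] = {"species": species, "location": location,
                                "workers": [], "ids": []}
            rows[colony]["workers"].append(geno)
            rows[colony]["ids"].append(worker or f"{colony}_w{len(rows[colony]['ids'])}")

    colonies = []
    for cid in order:
        info = rows[cid]
        observed: dict[str, set[int]] = {l.name: set() for l in panel}
        for w in info["workers"]:
            for locus, pair in zip(panel, w):
                if pair is not None:
                    observed[locus.name].update(pair)
        full_panel = [
            Locus(l.name, frozenset(observed[l.name]), l.missing_code) for l in panel
        ]
        colonies.append(
            ColonySample(
                colony_id=cid,
                species_id=info["species"],
                location=info["location"],
                panel=full_panel,
                workers=info["workers"],
                worker_ids=info["ids"],
            )
        )
    return colonies


def write_genotype_table(colonies: Sequence[ColonySample], path, dialect: str = "csv",
                         missing: str = "0/0") -> None:
    """Write colonies back to the tabular worker-genotype format."""
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    panel = colonies[0].panel
    for c in colonies:
        if [l.name for l in c.panel] != [l.name for l in panel]:
            raise ValueError("all colonies must share one locus panel")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["colony", "species", "location", "worker"] + [l.name for l in panel])
        for c in colonies:
            for wid, geno in zip(c.worker_ids, c.workers):
                cells = [
                    missing if pair is None else f"{pair[0]}/{pair[1]}" for pair in geno
                ]
                writer.writerow([c.colony_id, c.species_id, c.location, wid] + cells)


# ---------------------------------------------------------------------------
# GENEPOP output for deduced parents
# ---------------------------------------------------------------------------


def _genepop_digits(parents: Sequence[ParentSet]) -> int:
    max_allele = 0
    for p in parents:
        for pair in p.queen:
            if pair is not None:
                max_allele = max(max_allele, *pair)
        for m in p.males:
            for a in m:
                if a is not None:
                    max_allele = max(max_allele, a)
    if max_allele < 10 ** 3:
        return 3
    raise GenepopEncodingError(
        f"allele {max_allele} does not fit 3-digit GENEPOP coding"
    )


def write_genepop(parents: Sequence[ParentSet], path, title: str = "deduced parents") -> None:
    """Write deduced queens and males as a GENEPOP file, one POP per colony.

    Each haploid male is written as a homozygous diploid and each queen is
    written twice, so every parent contributes four gene copies and diploid
    downstream software weights queen and male genomes equally.
    """
    if not parents:
        raise ValueError("no parents to write")
    panel = parents[0].panel
    for p in parents:
        if [l.name for l in p.panel] != [l.name for l in panel]:
            raise ValueError("all parents must share one locus panel")
    digits = _genepop_digits(parents)

    def code(allele: Optional[int]) -> str:
        if allele is None:
            return "0" * (2 * digits)
        return f"{allele:0{digits}d}" * 2

    def code_pair(pair: Optional[tuple[int, int]]) -> str:
        if pair is None:
            return "0" * (2 * digits)
        return f"{pair[0]:0{digits}d}{pair[1]:0{digits}d}"

    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in panel:
            fh.write(locus.name + "\n")
        for p in parents:
            fh.write("POP\n")
            for dup in range(2):  # queen duplicated
                cells = " ".join(code_pair(pair) for pair in p.queen)
                fh.write(f"{p.colony_id}_queen, {cells}\n")
            for j, male in enumerate(p.males):
                cells = " ".join(code(a) for a in male)
                fh.write(f"{p.colony_id}_m{j}, {cells}\n")


def read_genepop(path) -> tuple[list[str], list[list[tuple[str, DiploidGenotype]]]]:
    """Read a GENEPOP file; returns (locus names, POP blocks of (id, genotype))."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GenotypeParseError(f"{path}: empty GENEPOP file")
    lines = lines[1:]  # title
    loci: list[str] = []
    i = 0
    while i < len(lines) and lines[i].strip().upper() != "POP":
        # locus names may be one per line or comma-separated
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    pops: list[list[tuple[str, DiploidGenotype]]] = []
    current: Optional[list[tuple[str, DiploidGenotype]]] = None
    for ln in lines[i:]:
        if ln.strip().upper() == "POP":
            if current is not None:
                pops.append(current)
            current = []
            continue
        if not ln.strip() or current is None:
            continue
        name, _, rest = ln.partition(",")
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"{path}: record {name.strip()!r} has {len(tokens)} loci, expected {len(loci)}"
            )
        geno: list[Optional[tuple[int, int]]] = []
        for tok in tokens:
            digits = len(tok) // 2
            a, b = int(tok[:digits]), int(tok[digits:])
            geno.append(None if a == 0 or b == 0 else sort_pair(a, b))
        current.append((name.strip(), tuple(geno)))
    if current is not None:
        pops.append(current)
    return loci, pops


# ---------------------------------------------------------------------------
# Allele frequencies from deduced parents
# ---------------------------------------------------------------------------


def allele_frequencies(
    parents: Sequence[ParentSet], weighting: str = "gene_copy"
) -> AlleleFrequencyTable:
    """Population allele frequencies from deduced queens and males.

    ``gene_copy`` counts what is actually there: one copy per male allele,
    two per queen.  ``duplicated_diploid`` mimics a diploid input file in
    which males are entered as homozygous diploids and queens duplicated
    (2 copies per male allele, 4 per queen), which double-weights every
    parent equally but is what legacy diploid software sees.
    """
    if weighting not in ("gene_copy", "duplicated_diploid"):
        raise ValueError(f"unknown weighting {weighting!r}")
    male_w, queen_w = (1.0, 1.0) if weighting == "gene_copy" else (2.0, 2.0)
    # queen_w multiplies each of the queen's two gene copies; duplication in
    # duplicated_diploid doubles both parents, so relative weights match FSTAT
    # input built from duplicated queens and homozygote males.
    panel = parents[0].panel
    loci = [l.name for l in panel]
    counts: dict[str, dict[int, float]] = {l: {} for l in loci}
    for p in parents:
        if [l.name for l in p.panel] != loci:
            raise ValueError("all parents must share one locus panel")
        for locus, pair in zip(loci, p.queen):
            if pair is None:
                continue
            for a in pair:
                counts[locus][a] = counts[locus].get(a, 0.0) + queen_w
        for male in p.males:
            for locus, a in zip(loci, male):
                if a is None:
                    continue
                counts[locus][a] = counts[locus].get(a, 0.0) + male_w
    kept, freqs = [], {}
    for locus in loci:
        total = sum(counts[locus].values())
        if total == 0:
            warnings.warn(f"locus {locus}: no typed parents, excluded from frequencies")
            continue
        kept.append(locus)
        freqs[locus] = {a: c / total for a, c in counts[locus].items()}
    return AlleleFrequencyTable(
        loci=kept, counts={l: counts[l] for l in kept}, freqs=freqs
    )


def write_frequency_table(table: AlleleFrequencyTable, path) -> None:
    """Tidy TSV of allele frequencies: locus, allele, count, frequency."""
    with open(path, "w") as fh:
        fh.write("locus\tallele\tcount\tfrequency\n")
        for locus in table.loci:
            for allele in sorted(table.freqs[locus]):
                fh.write(
                    f"{locus}\t{allele}\t{table.counts[locus][allele]:g}"
                    f"\t{table.freqs[locus][allele]:.10g}\n"
                )


def frequencies_from_counts(
    counts: Mapping[str, Mapping[int, float]]
) -> AlleleFrequencyTable:
    """Build a frequency table directly from per-locus allele counts."""
    loci = list(counts)
    cc = {l: dict(counts[l]) for l in loci}
    freqs = {}
    for l in loci:
        total = sum(cc[l].values())
        if total <= 0:
            raise ValueError(f"locus {l}: nonpositive total count")
        freqs[l] = {a: c / total for a, c in cc[l].items()}
    return AlleleFrequencyTable(loci=loci, counts=cc, freqs=freqs)
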