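"""Readers and writers for the tabular and sequence formats the pipeline touches.

Genotype tables are CSV with one row per individual, metadata columns
``id, colony, caste, ploidy`` and two allele columns per locus (suffixes
``.1``/``.2``).  Haploid individuals carry their single allele in the ``.1``
column and 0 in ``.2``.  The missing-allele code is 0 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = 0

CASTES = frozenset({"queen", "worker", "male", "alate_female", "dealate_queen"})
META_COLUMNS = ("id", "colony", "caste", "ploidy")

DIPLOID_CASTES = frozenset({"queen", "worker", "alate_female", "dealate_queen"})


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Colony-structured multilocus genotypes (diploid females, haploid males)."""

    data: pd.DataFrame
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        df = self.data
        for col in META_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing metadata column {col!r}")
        for locus in self.loci:
            for suffix in (".1", ".2"):
                if locus + suffix not in df.columns:
                    raise FormatError(f"missing allele column {locus + suffix!r}")
        bad_caste = set(df["caste"]) - CASTES
        if bad_caste:
            raise FormatError(f"unknown caste(s): {sorted(bad_caste)}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise FormatError(f"duplicate individual id {dup!r}")
        if (df["colony"].astype(str) == "").any():
            raise FormatError("empty colony id")
        if not df["ploidy"].isin((1, 2)).all():
            raise FormatError("ploidy must be 1 or 2")
        for locus in self.loci:
            a1 = df[locus + ".1"].to_numpy()
            a2 = df[locus + ".2"].to_numpy()
            dip = df["ploidy"].to_numpy() == 2
            half = dip & ((a1 == MISSING) != (a2 == MISSING))
            if half.any():
                row = df.loc[half, "id"].iloc[0]
                raise FormatError(
                    f"diploid individual {row!r} has a single allele call at locus {locus!r}"
                )
            hap_second = ~dip & (a2 != MISSING)
            if hap_second.any():
                row = df.loc[hap_second, "id"].iloc[0]
                raise FormatError(
                    f"haploid individual {row!r} has two allele calls at locus {locus!r}"
                )

    # -- accessors -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def colonies(self) -> list[str]:
        return list(dict.fromkeys(self.data["colony"]))

    def subset(self, mask) -> "GenotypeTable":
        return GenotypeTable(self.data.loc[mask].reset_index(drop=True), self.loci)

    def by_colony(self, colony: str) -> "GenotypeTable":
        return self.subset(self.data["colony"] == colony)

    def diploids(self) -> "GenotypeTable":
        return self.subset(self.data["ploidy"] == 2)

    def haploids(self) -> "GenotypeTable":
        return self.subset(self.data["ploidy"] == 1)

    def of_caste(self, *castes: str) -> "GenotypeTable":
        return self.subset(self.data["caste"].isin(castes))

    def genotype(self, ind_id: str) -> dict[str, tuple[int, ...]]:
        """Per-locus allele tuple for one individual (sorted; 0 = missing)."""
        row = self.data.loc[self.data["id"] == ind_id]
        if row.empty:
            raise KeyError(ind_id)
        return self._row_genotype(row.iloc[0])

    def _row_genotype(self, row: pd.Series) -> dict[str, tuple[int, ...]]:
        geno: dict[str, tuple[int, ...]] = {}
        ploidy = int(row["ploidy"])
        for locus in self.loci:
            a1, a2 = int(row[locus + ".1"]), int(row[locus + ".2"])
            if ploidy == 2:
                geno[locus] = tuple(sorted((a1, a2)))
            else:
                geno[locus] = (a1,)
        return geno

    def iter_genotypes(self) -> Iterator[tuple[str, str, str, dict[str, tuple[int, ...]]]]:
        """Yield (id, colony, caste, genotype dict) for every individual."""
        for _, row in self.data.iterrows():
            yield str(row["id"]), str(row["colony"]), str(row["caste"]), self._row_genotype(row)

    def allele_counts(self, locus: str, ids: Iterable[str] | None = None) -> dict[int, int]:
        """Counts of non-missing allele copies at ``locus`` (diploids count twice)."""
        df = self.data if ids is None else self.data[self.data["id"].isin(set(ids))]
        alleles: list[int] = []
        for _, row in df.iterrows():
            vals = [int(row[locus + ".1"])]
            if int(row["ploidy"]) == 2:
                vals.append(int(row[locus + ".2"]))
            alleles.extend(v for v in vals if v != MISSING)
        out: dict[int, int] = {}
        for a in alleles:
            out[a] = out.get(a, 0) + 1
        return out

    def missing_report(self) -> dict[str, int]:
        """Number of individuals with a missing call, per locus."""
        report = {}
        for locus in self.loci:
            miss = (self.data[locus + ".1"] == MISSING).sum()
            report[locus] = int(miss)
        return report


def table_from_records(records: list[dict], loci: Iterable[str]) -> GenotypeTable:
    """Build a GenotypeTable from dicts with keys id/colony/caste/ploidy/genotype.

    ``genotype`` maps locus name to an allele tuple (length 1 or 2).
    """
    loci = tuple(loci)
    rows = []
    for rec in records:
        row = {
            "id": rec["id"],
            "colony": rec["colony"],
            "caste": rec["caste"],
            "ploidy": rec["ploidy"],
        }
        geno = rec["genotype"]
        for locus in loci:
            alleles = geno.get(locus, (MISSING,) * rec["ploidy"])
            if len(alleles) == 1:
                row[locus + ".1"], row[locus + ".2"] = int(alleles[0]), MISSING
            else:
                a, b = sorted(int(x) for x in alleles)
                row[locus + ".1"], row[locus + ".2"] = a, b
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + [f"{l}{s}" for l in loci for s in (".1", ".2")])
    return GenotypeTable(df, loci)


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read the CSV genotype dialect; validates structure and returns the table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"id": str, "colony": str, "caste": str})
    loci = []
    for col in df.columns:
        if col.endswith(".1"):
            locus = col[:-2]
            if locus + ".2" not in df.columns:
                raise FormatError(f"locus {locus!r} has column {col!r} but no {locus + '.2'!r}")
            loci.append(locus)
    if not loci:
        raise FormatError("no locus columns found (expect '<locus>.1'/'<locus>.2')")
    for locus in loci:
        for suffix in (".1", ".2"):
            df[locus + suffix] = df[locus + suffix].fillna(MISSING).astype(int)
    df["ploidy"] = df["ploidy"].astype(int)
    return GenotypeTable(df, tuple(loci))


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GENEPOP dialect
# ---------------------------------------------------------------------------


def write_genepop(
    table: GenotypeTable,
    path: str | Path | None = None,
    pop_by: str = "colony",
    title: str = "nestkin export",
) -> tuple[str, dict[str, dict[int, int]]]:
    """Serialize diploid genotypes to the GENEPOP dialect.

    Alleles are recoded per locus by ascending size to codes 001, 002, ...;
    the recoding map ``{locus: {allele_size: code}}`` is returned alongside the
    text.  Haploid individuals are rejected (GENEPOP is diploid-only here).
    """
    if (table.data["ploidy"] == 1).any():
        bad = table.data.loc[table.data["ploidy"] == 1, "id"].iloc[0]
        raise FormatError(f"haploid individual {bad!r} cannot be written to GENEPOP")
    recode: dict[str, dict[int, int]] = {}
    for locus in table.loci:
        sizes = sorted(set(table.allele_counts(locus)))
        if len(sizes) > 999:
            raise FormatError(f"locus {locus!r} has more than 999 alleles")
        recode[locus] = {size: i + 1 for i, size in enumerate(sizes)}
    lines = [title]
    lines.extend(table.loci)
    for pop in dict.fromkeys(table.data[pop_by]):
        lines.append("Pop")
        sub = table.data[table.data[pop_by] == pop]
        for _, row in sub.iterrows():
            codes = []
            for locus in table.loci:
                a1, a2 = int(row[locus + ".1"]), int(row[locus + ".2"])
                c1 = recode[locus].get(a1, 0)
                c2 = recode[locus].get(a2, 0)
                codes.append(f"{c1:03d}{c2:03d}")
            lines.append(f"{row['id']} , " + " ".join(codes))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text, recode


def read_genepop(source: str | Path) -> GenotypeTable:
    """Parse the GENEPOP dialect written by :func:`write_genepop`.

    Returns a diploid GenotypeTable whose allele values are the (recoded)
    integer codes; population blocks become colony ids ``pop1``, ``pop2``, ...
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError("truncated GENEPOP input")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        loci.extend(l.strip() for l in lines[i].split(","))
        i += 1
    if i == len(lines):
        raise FormatError("no 'Pop' separator found")
    records = []
    pop_idx = 0
    for line in lines[i:]:
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise FormatError(f"malformed individual line: {line!r}")
        ind_id, rest = line.split(",", 1)
        codes = rest.split()
        if len(codes) != len(loci):
            raise FormatError(f"individual {ind_id.strip()!r} has {len(codes)} genotypes, expected {len(loci)}")
        geno = {}
        for locus, code in zip(loci, codes):
            if len(code) not in (4, 6):
                raise FormatError(f"bad genotype code {code!r} at locus {locus!r}")
            half = len(code) // 2
            geno[locus] = (int(code[:half]), int(code[half:]))
        records.append(
            {
                "id": ind_id.strip(),
                "colony": f"pop{pop_idx + 1}",
                "caste": "worker",
                "ploidy": 2,
                "genotype": geno,
            }
        )
    return table_from_records(records, loci)


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read the colony coordinate CSV (columns: colony, x, y[, position_km])."""
    df = pd.read_csv(path, dtype={"colony": str})
    for col in ("colony", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"coordinate table missing column {col!r}")
    if df["colony"].duplicated().any():
        raise FormatError("duplicate colony id in coordinate table")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise FormatError("non-finite coordinates")
    return df


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

_ALLOWED = set("ACGTN")


@dataclass
class HaplotypeAlignment:
    """Gap-free equal-length nucleotide sequences keyed by sequence id."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.sequences = tuple(s.upper() for s in self.sequences)
        if not self.ids:
            raise FormatError("empty alignment")
        if len(self.ids) != len(self.sequences):
            raise FormatError("ids/sequences length mismatch")
        L = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != L:
                raise FormatError(f"sequence {sid!r} has length {len(seq)}, expected {L}")
            bad = set(seq) - _ALLOWED
            if "-" in seq:
                raise FormatError(f"sequence {sid!r} contains gap characters")
            if bad:
                raise FormatError(f"sequence {sid!r} contains invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))


def read_fasta_alignment(path: str | Path) -> HaplotypeAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in {path}")
    return HaplotypeAlignment(
        ids=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
    )


def write_fasta(alignment: HaplotypeAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in alignment]
    SeqIO.write(records, str(path), "fasta")
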