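"""Sequence data model, alignment windows, haplotype collapsing and translation.

This module is the preprocessing layer of the toolkit: validated IUPAC DNA
records with sample metadata, trimming of ragged multi-study alignments to a
common analysis window, collapsing of identical resolved sequences into
haplotypes with per-population counts, and in-frame translation under a
configurable genetic code (invertebrate mitochondrial, NCBI table 5, by
default).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMBIGUITY_SETS",
    "CODE_FOR_SET",
    "DNA_ALPHABET",
    "GAP",
    "MISSING",
    "SequenceRecord",
    "AlignedMatrix",
    "RegionDef",
    "REGIONS",
    "Haplotype",
    "HaplotypeTable",
    "TrimReport",
    "GeneticCode",
    "iupac_union",
    "iupac_overlay",
    "trim_to_common_window",
    "collapse_haplotypes",
    "translate",
    "infer_frame",
    "find_primer",
    "strip_primers",
    "read_sample_sheet",
    "write_sample_sheet",
]

GAP = "-"
#: per-base sets for every IUPAC DNA code (A..N), uppercase
AMBIGUITY_SETS: dict[str, frozenset[str]] = {
    code.upper(): frozenset(bases.upper())
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if code.upper() != "X"
}
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in AMBIGUITY_SETS.items()}
DNA_ALPHABET = frozenset(AMBIGUITY_SETS) | {GAP}
MISSING = frozenset({GAP, "N"})
UNAMBIGUOUS = frozenset("ACGT")


def iupac_union(a: str, b: str) -> str:
    """IUPAC code covering the union of the base sets of two codes."""
    return CODE_FOR_SET[AMBIGUITY_SETS[a] | AMBIGUITY_SETS[b]]


def iupac_overlay(a: str, b: str) -> str:
    """Position-wise IUPAC union of two sequences, truncated to the shorter.

    This is the in-silico analogue of a chromatogram with superimposed double
    peaks: two templates read simultaneously, each position showing every
    base present in either template.
    """
    return "".join(iupac_union(x, y) for x, y in zip(a, b))


class AlphabetError(ValueError):
    """A residue outside the IUPAC DNA alphabet (+ gap) was encountered."""


@dataclass
class SequenceRecord:
    """One DNA sequence with its sample metadata."""

    id: str
    residues: str
    farm: str | None = None
    country: str | None = None
    marker: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise AlphabetError(f"{self.id}: invalid residues {sorted(bad)}")


class AlignedMatrix:
    """Ordered, equal-length sequence records (a pre-aligned matrix)."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("empty alignment")
        length = len(records[0].residues)
        ids = set()
        for rec in records:
            if len(rec.residues) != length:
                raise ValueError(
                    f"{rec.id}: length {len(rec.residues)} != {length}"
                )
            if rec.id in ids:
                raise ValueError(f"duplicate id {rec.id!r}")
            ids.add(rec.id)
        self.records = records

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def seqs(self) -> list[str]:
        return [r.residues for r in self.records]

    def __iter__(self):
        return iter(self.records)

    def get(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def window(self, start: int, stop: int) -> "AlignedMatrix":
        """Column slice [start, stop) as a new matrix (metadata preserved)."""
        if not (0 <= start < stop <= self.length):
            raise ValueError(f"invalid window [{start}, {stop})")
        return AlignedMatrix(
            [
                SequenceRecord(r.id, r.residues[start:stop], r.farm, r.country, r.marker)
                for r in self.records
            ]
        )

    def subset(self, keep_ids: Iterable[str]) -> "AlignedMatrix":
        keep = set(keep_ids)
        return AlignedMatrix([r for r in self.records if r.id in keep])

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_fasta(
        cls, path: str | Path, sample_sheet: str | Path | None = None
    ) -> "AlignedMatrix":
        """Read a FASTA alignment; metadata from a sample sheet TSV when given,
        otherwise from ``id|farm|country|marker`` headers when present."""
        meta: dict[str, dict] = {}
        if sample_sheet is not None:
            meta = read_sample_sheet(sample_sheet)
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = rec.id.split("|")
            seq_id = fields[0]
            info = dict(meta.get(seq_id, {}))
            if not info and len(fields) == 4:
                info = {"farm": fields[1], "country": fields[2], "marker": fields[3]}
            records.append(
                SequenceRecord(
                    seq_id,
                    str(rec.seq),
                    farm=info.get("farm"),
                    country=info.get("country"),
                    marker=info.get("marker"),
                )
            )
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path, with_metadata: bool = False) -> None:
        recs = []
        for r in self.records:
            name = r.id
            if with_metadata:
                name = "|".join(
                    [r.id, r.farm or ".", r.country or ".", r.marker or "."]
                )
            recs.append(SeqRecord(Seq(r.residues), id=name, description=""))
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fasta")  # Biopython wraps at 60 columns


def read_sample_sheet(path: str | Path) -> dict[str, dict]:
    """Sample sheet TSV with columns: id, farm, country, marker."""
    meta: dict[str, dict] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            row = dict(zip(header, parts))
            meta[row["id"]] = {
                "farm": row.get("farm"),
                "country": row.get("country"),
                "marker": row.get("marker"),
            }
    return meta


def write_sample_sheet(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tfarm\tcountry\tmarker\n")
        for r in records:
            fh.write(
                f"{r.id}\t{r.farm or '.'}\t{r.country or '.'}\t{r.marker or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Region model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionDef:
    """One of the two independently analysed CO1 amplicons."""

    name: str
    primer_forward: str
    primer_reverse: str
    expected_length_bp: int
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.expected_length_bp <= 0:
            raise ValueError("expected_length_bp must be positive")
        if not self.primer_forward or not self.primer_reverse:
            raise ValueError("primers must be non-empty")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")


#: the two CO1 amplicons used across the pooled mite studies
REGIONS = {
    "region1": RegionDef(
        "region1",
        primer_forward="GAAAGAGGAGCAGGCACTGG",  # CO1LCF
        primer_reverse="CCAGTAATACCTCCAATTGTAAAT",  # RQCOIR
        expected_length_bp=470,
    ),
    "region2": RegionDef(
        "region2",
        primer_forward="TGATTTTTTGGTCACCCAGAAG",  # COX1F
        primer_reverse="TACAGCTCCTATAGATAAAAC",  # COX1R
        expected_length_bp=273,
    ),
}

_COMPLEMENT = str.maketrans("ACGTMRWSYKVHDBN-", "TGCAKYWSRMBDHVN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_site_match(base: str, primer_code: str) -> bool:
    return AMBIGUITY_SETS.get(base, frozenset()) <= AMBIGUITY_SETS.get(
        primer_code, frozenset()
    )


def find_primer(seq: str, primer: str, max_mismatch: int = 1) -> int | None:
    """Leftmost start of an exact-or-``max_mismatch`` primer match, else None.

    Primer IUPAC codes match any base they cover.
    """
    L = len(primer)
    best = None
    for start in range(0, len(seq) - L + 1):
        mm = 0
        for b, p in zip(seq[start : start + L], primer):
            if not _iupac_site_match(b, p):
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            best = start
            break
    return best


def strip_primers(seq: str, region: RegionDef, max_mismatch: int = 1) -> str:
    """Remove forward and (reverse-complemented) reverse primer sequences."""
    out = seq
    f = find_primer(out, region.primer_forward, max_mismatch)
    if f is not None:
        out = out[f + len(region.primer_forward) :]
    r = find_primer(out, revcomp(region.primer_reverse), max_mismatch)
    if r is not None:
        out = out[:r]
    return out


# ---------------------------------------------------------------------------
# Trimming to a common window
# ---------------------------------------------------------------------------


@dataclass
class TrimReport:
    policy: str
    window: tuple[int, int]
    dropped_rows: list[tuple[str, str]] = field(default_factory=list)
    n_input_rows: int = 0
    n_input_cols: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "policy": self.policy,
                "window": list(self.window),
                "dropped_rows": [list(t) for t in self.dropped_rows],
                "n_input_rows": self.n_input_rows,
                "n_input_cols": self.n_input_cols,
            },
            sort_keys=True,
        )


def _column_coverage(aln: AlignedMatrix, col: int, missing: frozenset[str]) -> float:
    ok = sum(1 for r in aln.records if r.residues[col] not in missing)
    return ok / aln.n


def trim_to_common_window(
    aln: AlignedMatrix,
    policy: str = "trim_columns",
    min_coverage: float = 1.0,
    missing: frozenset[str] = MISSING,
) -> tuple[AlignedMatrix, TrimReport]:
    """Reduce a ragged multi-study alignment to a fully comparable window.

    ``trim_columns``
        keep the maximal contiguous column interval where at least
        ``min_coverage`` of rows carry data (non-gap, non-N); rows that still
        have missing data inside that window are dropped and logged.
    ``drop_sequences``
        keep the full column span and drop rows whose flanks are padded with
        missing data (the merged-study convention pads non-overlapping flanks
        with N).

    ``missing`` is the set of characters treated as absent data: gap and N
    by default (ragged merged alignments); pass ``frozenset({"N"})`` for
    curated alignments where internal gaps are real indel variation.
    """
    if not (0 < min_coverage <= 1):
        raise ValueError("min_coverage must be in (0, 1]")
    report = TrimReport(policy, (0, aln.length), [], aln.n, aln.length)

    if policy == "trim_columns":
        good = [
            _column_coverage(aln, c, missing) >= min_coverage
            for c in range(aln.length)
        ]
        best_start = best_stop = 0
        start = None
        for c, flag in enumerate(good + [False]):
            if flag and start is None:
                start = c
            elif not flag and start is not None:
                if c - start > best_stop - best_start:
                    best_start, best_stop = start, c
                start = None
        if best_stop == best_start:
            raise ValueError("no column satisfies min_coverage: empty window")
        window = aln.window(best_start, best_stop)
        keep, dropped = [], []
        for rec in window.records:
            if set(rec.residues) & missing:
                dropped.append((rec.id, "missing_data_in_window"))
            else:
                keep.append(rec)
        if not keep:
            raise ValueError("all rows dropped inside the trimmed window")
        report.window = (best_start, best_stop)
        report.dropped_rows = dropped
        return AlignedMatrix(keep), report

    if policy == "drop_sequences":
        keep, dropped = [], []
        for rec in aln.records:
            s = rec.residues
            flank = (s[0] in missing) or (s[-1] in missing)
            if flank:
                dropped.append((rec.id, "flanking_missing_data"))
            else:
                keep.append(rec)
        if not keep:
            raise ValueError("all rows dropped")
        report.dropped_rows = dropped
        return AlignedMatrix(keep), report

    raise ValueError(f"unknown policy {policy!r}")


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    id: str
    sequence: str
    members: list[str]
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class HaplotypeTable:
    """Unique resolved sequences over an analysis window, with counts."""

    haplotypes: list[Haplotype]
    excluded: list[tuple[str, str]]
    window: tuple[int, int]

    @property
    def n_retained(self) -> int:
        return sum(h.total for h in self.haplotypes)

    @property
    def populations(self) -> list[str]:
        pops: list[str] = []
        for h in self.haplotypes:
            for p in h.counts:
                if p not in pops:
                    pops.append(p)
        return pops

    def get(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.id == hap_id:
                return h
        raise KeyError(hap_id)

    def restrict(self, population: str) -> "HaplotypeTable":
        haps = [
            Haplotype(h.id, h.sequence, list(h.members), {population: h.counts[population]})
            for h in self.haplotypes
            if h.counts.get(population, 0) > 0
        ]
        return HaplotypeTable(haps, [], self.window)

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("haplotype\tsequence\tfarm\tcount\n")
            for h in self.haplotypes:
                for pop in sorted(h.counts):
                    fh.write(f"{h.id}\t{h.sequence}\t{pop}\t{h.counts[pop]}\n")


def collapse_haplotypes(
    aln: AlignedMatrix,
    window: tuple[int, int] | None = None,
    ambiguity_policy: str = "exclude",
    gap_policy: str = "exclude",
    hap_prefix: str = "Hap",
) -> HaplotypeTable:
    """Merge identical resolved sequences into haplotypes.

    Rows containing ambiguity codes (and, under the default policy, gaps)
    inside the window are excluded and logged rather than being
    compatibility-matched — mirroring the exclusion of unreliable
    double-peak reads upstream. Counts are partitioned by population (farm).
    """
    if window is None:
        window = (0, aln.length)
    start, stop = window
    if not (0 <= start < stop <= aln.length):
        raise ValueError(f"window {window} outside alignment")

    order: list[str] = []
    groups: dict[str, Haplotype] = {}
    excluded: list[tuple[str, str]] = []
    for rec in aln.records:
        s = rec.residues[start:stop]
        chars = set(s)
        ambiguous = bool(chars - UNAMBIGUOUS - {GAP})
        gapped = GAP in chars
        if ambiguous and ambiguity_policy == "exclude":
            excluded.append((rec.id, "ambiguity"))
            continue
        if gapped and gap_policy == "exclude":
            excluded.append((rec.id, "gap"))
            continue
        pop = rec.farm or "?"
        if s not in groups:
            hap = Haplotype(f"{hap_prefix}{len(order) + 1}", s, [], {})
            groups[s] = hap
            order.append(s)
        hap = groups[s]
        hap.members.append(rec.id)
        hap.counts[pop] = hap.counts.get(pop, 0) + 1

    if not order:
        raise ValueError("zero rows retained after ambiguity/gap exclusion")
    return HaplotypeTable([groups[s] for s in order], excluded, window)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------


class GeneticCode:
    """An NCBI translation table with an explicit stop-codon set.

    The default is table 5 (invertebrate mitochondrial), under which TGA
    codes tryptophan and only TAA/TAG are stops.
    """

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stop_codons = frozenset(table.stop_codons)
        self.codon_map = dict(table.forward_table)
        for stop in self.stop_codons:
            self.codon_map[stop] = "*"
        if len(self.codon_map) != 64:
            raise ValueError("incomplete codon table")

    def aa(self, codon: str) -> str:
        return self.codon_map.get(codon, "X")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


MITO_CODE = GeneticCode(5)


def translate(
    seq: str,
    code: GeneticCode = MITO_CODE,
    frame_offset: int = 0,
) -> tuple[str, list[int]]:
    """Translate, returning (amino acids, 0-based codon indices of stops).

    Gaps are stripped before translation (a frameshifting indel therefore
    shifts every downstream codon); a trailing partial codon is ignored.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    s = seq.replace(GAP, "").upper()
    bad = set(s) - frozenset(AMBIGUITY_SETS)
    if bad:
        raise AlphabetError(f"invalid residues {sorted(bad)}")
    s = s[frame_offset:]
    if len(s) < 3:
        raise ValueError("fewer than 3 nucleotides after frame offset")
    aas, stops = [], []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        a = code.aa(codon)
        if a == "*":
            stops.append(i // 3)
        aas.append(a)
    return "".join(aas), stops


def infer_frame(
    seqs: Iterable[str], code: GeneticCode = MITO_CODE
) -> tuple[int, bool]:
    """Frame minimizing total in-frame stops over a panel; ties favour 0.

    Returns (frame, warning) where warning is True when no frame is
    stop-free for any panel member.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty panel")
    totals = []
    stop_free_any = []
    for f in (0, 1, 2):
        counts = [len(translate(s, code, f)[1]) for s in seqs]
        totals.append(sum(counts))
        stop_free_any.append(any(c == 0 for c in counts))
    best = min(range(3), key=lambda f: (totals[f], f))
    warning = not any(stop_free_any)
    return best, warning
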