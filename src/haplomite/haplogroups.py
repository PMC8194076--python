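"""Haplogroup assignment and the published naming-scheme synonymy.

Successive studies of this mite named the same mitochondrial lineages with
different identifiers (Lmt1/Lmt2/Lmt3, A/B/C, clade E/F, L1, JOW...).  The
bundled synonymy maps every published identifier to a canonical label with a
taxonomic status: A/B/C are the typical intraspecific haplogroups, D is the
cryptic sister species (lineage L1), and E, F, H, JOW and Co21-22 are
nuclear-pseudogene (NUMT) artifact groups.

Assignment of query haplotypes is by nearest reference p-distance with an
unassignability threshold; the tree-based cross-check lives in
``phylo_diag``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "CANONICAL_STATUS",
    "SYNONYMY",
    "UnknownIdentifierError",
    "synonymize",
    "ReferencePanel",
    "Assignment",
    "assign",
    "p_distance",
]

#: canonical label -> taxonomic status
CANONICAL_STATUS = {
    "A": "typical",
    "B": "typical",
    "C": "typical",
    "D": "cryptic",
    "E": "numt",
    "F": "numt",
    "H": "numt",
    "JOW": "numt",
    "Co21-22": "numt",
}

#: per-study identifier -> canonical label.  Scheme keys: RO0/RO1 (the two
#: founding morpho-molecular studies), OB (the A/B/C definition), RB (the
#: Lmt/Bayesian-cluster study), CHU, KT, CIL (later regional studies) and
#: "present" (the pooled analysis itself).
SYNONYMY: dict[str, dict[str, str]] = {
    "RO0": {"Clade E": "Co21-22", "clade F": "D"},
    "RO1": {
        "Co21 & Co22": "Co21-22",
        "JOW": "JOW",
        "Lmt3": "A",
        "Lmt2": "B",
        "Lmt1": "C",
        "L1": "D",
    },
    "OB": {"A": "A", "B": "B", "C": "C", "D": "D"},
    "RB": {"Lmt3": "A", "Lmt2": "B", "Lmt1": "C", "L1": "D"},
    "CHU": {"A": "A", "B": "B", "C": "C", "D": "D"},
    "KT": {"A": "A", "B": "B", "C": "C", "D": "D"},
    "CIL": {"A": "A", "B": "B", "C": "C", "D": "D", "E": "E", "F": "F"},
    "present": {label: label for label in CANONICAL_STATUS},
}


class UnknownIdentifierError(KeyError):
    """An identifier absent from the bundled synonymy (never guessed)."""


def synonymize(identifier: str, scheme: str) -> tuple[str, str]:
    """Map a published identifier to (canonical label, status)."""
    if scheme not in SYNONYMY:
        raise UnknownIdentifierError(f"unknown scheme {scheme!r}")
    table = SYNONYMY[scheme]
    if identifier not in table:
        raise UnknownIdentifierError(
            f"identifier {identifier!r} not in scheme {scheme!r}"
        )
    label = table[identifier]
    return label, CANONICAL_STATUS[label]


# ---------------------------------------------------------------------------
# nearest-reference assignment
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over positions where both sequences
    carry an unambiguous base."""
    same = diff = 0
    for x, y in zip(a, b):
        if x in _ACGT and y in _ACGT:
            if x == y:
                same += 1
            else:
                diff += 1
    total = same + diff
    if total == 0:
        raise ValueError("no comparable (unambiguous) positions")
    return diff / total


@dataclass
class ReferencePanel:
    """Labelled reference haplotypes with per-label status."""

    references: dict[str, str]  # reference id -> sequence
    labels: dict[str, str]  # reference id -> canonical label
    statuses: dict[str, str]  # label -> status

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("empty reference panel")
        for rid in self.references:
            if rid not in self.labels:
                raise ValueError(f"reference {rid!r} has no label")

    def by_status(self, status: str) -> dict[str, str]:
        return {
            rid: seq
            for rid, seq in self.references.items()
            if self.statuses.get(self.labels[rid]) == status
        }

    @classmethod
    def from_synth(cls, panel, include_outgroups: bool = True) -> "ReferencePanel":
        """Build from a synthetic haplogroup panel (generator centroids;
        the bundled default — real panels load from FASTA + TSV)."""
        refs, labels, statuses = {}, {}, {}
        for label, seq in panel.centroids.items():
            rid = f"ref_{label}"
            refs[rid] = seq
            labels[rid] = label
            statuses[label] = "cryptic" if label == "D" else "typical"
        if include_outgroups:
            for name, seq in panel.outgroups.items():
                refs[name] = seq
                labels[name] = name
                statuses[name] = "outgroup"
        return cls(refs, labels, statuses)

    @classmethod
    def from_files(cls, fasta: str | Path, labels_tsv: str | Path) -> "ReferencePanel":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        labels, statuses = {}, {}
        with open(labels_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                labels[row["id"]] = row["label"]
                statuses[row["label"]] = row["status"]
        return cls(seqs, labels, statuses)


@dataclass
class Assignment:
    haplotype_id: str
    nearest_label: str
    distance: float
    call: str


def assign(
    haplotypes: dict[str, str],
    panel: ReferencePanel,
    tau_assign: float = 0.03,
) -> dict[str, Assignment]:
    """Nearest-reference call per haplotype.

    Distances above ``tau_assign`` (chosen between the 1-2 mutation star
    scale and the percent-scale intergroup divergence) yield
    ``atypical_unassigned``.  Outgroup references are excluded from the
    nearest-reference search.
    """
    usable = {
        rid: seq
        for rid, seq in panel.references.items()
        if panel.statuses.get(panel.labels[rid]) != "outgroup"
    }
    if not usable:
        raise ValueError("reference panel has no assignable references")
    out: dict[str, Assignment] = {}
    for hid, seq in haplotypes.items():
        best_label, best_d = None, None
        for rid, ref in usable.items():
            d = p_distance(seq, ref)
            if best_d is None or d < best_d:
                best_d, best_label = d, panel.labels[rid]
        assert best_label is not None and best_d is not None
        if best_d > tau_assign:
            call = "atypical_unassigned"
        else:
            status = panel.statuses.get(best_label, "typical")
            call = f"{status}_{best_label}"
        out[hid] = Assignment(hid, best_label, best_d, call)
    return out


def write_assignments_tsv(assignments: dict[str, Assignment], path, header_lines=()):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("haplotype\tlabel\tdistance\tcall\n")
        for hid in assignments:
            a = assignments[hid]
            fh.write(f"{a.haplotype_id}\t{a.nearest_label}\t{a.distance:.6f}\t{a.call}\n")
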