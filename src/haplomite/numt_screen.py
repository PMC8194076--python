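"""Composite NUMT-pseudogene screening.

Five warning indicators are evaluated per candidate haplotype group within
a building, mirroring the QC checklist for mitochondrial barcoding of this
mite:

W1  amino-acid signal — several segregating amino-acid differences against
    the reference panel, and/or resolution retained on first codon
    positions only (functional groups lose it there);
W2  tree discordance — the group places among the outgroup species rather
    than inside the clade of the species' typical references;
W3  balanced multiplicity — multiple related haplotypes in one building at
    balanced frequencies (Hd above threshold) without a star pattern;
W4  chromatogram proxy — an excess of sequences dense in IUPAC ambiguity
    codes (the double-peak signature of co-amplification);
W5  nuclear sharing — a divergent mitochondrial group whose carriers share
    nuclear (Tpm) alleles with carriers of typical haplogroups cannot be a
    reproductively isolated lineage.

The composite verdict: any in-frame stop codon forces ``numt_suspect``;
otherwise two or more of W1-W4 force it; otherwise a divergent group is a
``cryptic_candidate`` when its nuclear alleles are private and a
``numt_suspect`` when they are shared; otherwise ``typical``.  Groups firing
exactly one warning are flagged for manual review.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .phylo_diag import DiagTree, RetentionRow
from .seq_core import GAP, GeneticCode, MITO_CODE, translate

__all__ = [
    "ScreenConfig",
    "NumtVerdict",
    "aa_segregating_vs_panel",
    "warning_w1",
    "warning_w2",
    "warning_w3",
    "warning_w4",
    "warning_w5_and_verdict",
]

_UNAMB = frozenset("ACGT")

W1 = "W1_aa_and_pos1"
W2 = "W2_tree_discordance"
W3 = "W3_balanced_multiplicity"
W4 = "W4_ambiguity_signal"
W5 = "W5_nuclear_sharing_absent_divergence"


@dataclass(frozen=True)
class ScreenConfig:
    tau_hd: float = 0.70  # within-building Hd threshold (W3)
    tau_aa_seg: int = 3  # "several" amino-acid segregating differences (W1)
    tau_assign: float = 0.03  # divergence threshold (shared with haplogroups)
    tau_ambig: float = 0.02  # per-sequence ambiguity fraction (W4)
    tau_ambig_seq_frac: float = 0.10  # fraction of building sample over tau_ambig
    tau_star: float = 0.5  # star score below which W3 can fire
    tau_support: float = 70.0  # shared with phylo_diag
    tau_stem: float = 0.5  # shared with phylo_diag
    min_stem_pos1: float = 0.015  # pos1 stem floor: >=3 steps on ~157 sites ("long branch")
    min_sample: int = 20  # guidance: intensive-sampling flag for W3
    genetic_code: int = 5
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tau_hd <= 1):
            raise ValueError("tau_hd must be in (0, 1]")
        if self.tau_aa_seg < 1:
            raise ValueError("tau_aa_seg must be >= 1")
        if not (0 <= self.tau_ambig <= 1 and 0 <= self.tau_ambig_seq_frac <= 1):
            raise ValueError("ambiguity thresholds must be fractions")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass
class NumtVerdict:
    group_id: str
    warnings: set[str]
    stop_codon_present: bool
    verdict: str  # typical | cryptic_candidate | numt_suspect
    rationale: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# W1: amino-acid segregating differences and/or pos1 resolution retention
# ---------------------------------------------------------------------------


def aa_segregating_vs_panel(
    group_seqs: Sequence[str],
    panel_seqs: Sequence[str],
    code: GeneticCode = MITO_CODE,
    frame_offset: int = 0,
) -> int:
    """Number of amino-acid positions where at least one group member shows
    a state absent from every panel reference."""
    panel_aa = [translate(s, code, frame_offset)[0] for s in panel_seqs]
    group_aa = [translate(s, code, frame_offset)[0] for s in group_seqs]
    n_pos = min(len(a) for a in panel_aa + group_aa)
    seg = 0
    for p in range(n_pos):
        panel_states = {a[p] for a in panel_aa} | {"X"}
        if any(a[p] not in panel_states for a in group_aa):
            seg += 1
    return seg


def warning_w1(
    group_seqs: Sequence[str],
    panel_seqs: Sequence[str],
    retention: RetentionRow | None,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[bool, bool, int]:
    """Returns (fired, stop_codon_present, n_aa_segregating).

    Stop codons are recorded separately (they override the composite rule
    downstream); the warning itself fires on amino-acid segregating
    differences or on retained first-position resolution — the latter
    catching stop-free pseudogenes, since the absence of stop codons is not
    evidence of functionality.
    """
    code = GeneticCode(config.genetic_code)
    stop_present = any(
        bool(translate(s, code, config.frame_offset)[1]) for s in group_seqs
    )
    n_aa = aa_segregating_vs_panel(group_seqs, panel_seqs, code, config.frame_offset)
    retained = bool(retention.retained and not retention.degenerate) if retention else False
    fired = (n_aa >= config.tau_aa_seg) or retained
    return fired, stop_present, n_aa


# ---------------------------------------------------------------------------
# W2: placement among outgroups
# ---------------------------------------------------------------------------


def warning_w2(
    tree: DiagTree,
    group: set[str],
    typical_refs: set[str],
    outgroups: set[str],
) -> tuple[bool, str]:
    """Fired when the minimal clade (bipartition side) containing the
    typical references together with the whole group also contains an
    outgroup taxon — i.e. the group sits on the outgroup side of the
    species clade.  A sister lineage to the typical clade does not fire.
    """
    if len(outgroups) < 2:
        raise ValueError("need >= 2 outgroup taxa in the tree")
    taxa = frozenset(tree.taxa)
    need = typical_refs | group
    sides = []
    for key in tree.lengths:
        sides.append(set(key))
        sides.append(set(taxa - key))
    # tip edges define trivial sides too
    for t in taxa:
        sides.append(set(taxa - {t}))
    containing = [s for s in sides if need <= s and len(s) < len(taxa)]
    if not containing:
        return False, "indeterminate: no proper clade contains group and references"
    minimal = min(containing, key=len)
    if minimal & outgroups:
        return True, "group clusters with outgroup taxa beyond the typical clade"
    return False, "group nested with the typical references"


# ---------------------------------------------------------------------------
# W3: balanced multiplicity within a building
# ---------------------------------------------------------------------------


def warning_w3(
    hd: float,
    star: float,
    n: int,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[bool, bool]:
    """Returns (fired, low_n_flag): balanced multiple haplotypes (high Hd,
    no star pattern).  ``low_n_flag`` marks samples below the recommended
    ~20 individuals per henhouse."""
    if n < 2:
        raise ValueError("n must be >= 2")
    fired = (hd > config.tau_hd) and (star < config.tau_star)
    return fired, n < config.min_sample


# ---------------------------------------------------------------------------
# W4: ambiguity-code density (chromatogram double-peak proxy)
# ---------------------------------------------------------------------------


def _ambiguity_fraction(seq: str) -> float:
    informative = [c for c in seq if c not in (GAP, "N")]
    if not informative:
        return 0.0
    return sum(1 for c in informative if c not in _UNAMB) / len(informative)


def warning_w4(
    raw_seqs: Sequence[str],
    config: ScreenConfig = ScreenConfig(),
) -> bool:
    """Fired when more than ``tau_ambig_seq_frac`` of the building's raw
    (pre-exclusion) sequences exceed the per-sequence ambiguity fraction."""
    if not raw_seqs:
        return False
    dense = sum(1 for s in raw_seqs if _ambiguity_fraction(s) > config.tau_ambig)
    return dense / len(raw_seqs) > config.tau_ambig_seq_frac


# ---------------------------------------------------------------------------
# W5 + composite verdict
# ---------------------------------------------------------------------------


def warning_w5_and_verdict(
    group_id: str,
    fired: dict[str, bool],
    stop_codon_present: bool,
    divergent: bool,
    nuclear_shared: bool | None,
    config: ScreenConfig = ScreenConfig(),
) -> NumtVerdict:
    """Combine the warnings into a verdict.

    ``nuclear_shared`` is True when the group's carriers share nuclear
    alleles with carriers of typical haplogroups, False when their alleles
    are private, None when nuclear data are unavailable.
    """
    warnings_fired = {w for w, f in fired.items() if f and w in {W1, W2, W3, W4}}
    rationale: list[str] = [f"{w} fired" for w in sorted(warnings_fired)]
    flags: list[str] = []
    if nuclear_shared is None:
        flags.append("nuclear data unavailable")

    if divergent and nuclear_shared is True:
        warnings_fired = warnings_fired | {W5}
        rationale.append(f"{W5} fired: divergent group shares nuclear alleles")

    if stop_codon_present:
        verdict = "numt_suspect"
        rationale.append("in-frame stop codon(s): loss of function certain")
    elif len(warnings_fired - {W5}) >= 2:
        verdict = "numt_suspect"
        rationale.append(">=2 mitochondrial warnings")
    elif divergent:
        if nuclear_shared is True:
            verdict = "numt_suspect"
        elif nuclear_shared is False:
            verdict = "cryptic_candidate"
            rationale.append("divergent group with private nuclear alleles")
        else:
            verdict = "cryptic_candidate"
            rationale.append("divergent group; nuclear corroboration missing")
    else:
        verdict = "typical"
        if len(warnings_fired) == 1:
            flags.append("review manually: single warning")
    return NumtVerdict(group_id, warnings_fired, stop_codon_present, verdict,
                       rationale, flags)


def write_verdicts(verdicts: list[NumtVerdict], tsv_path=None, json_path=None,
                   header_lines=()) -> None:
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("group\tverdict\tstop_codons\twarnings\tflags\trationale\n")
            for v in verdicts:
                fh.write(
                    f"{v.group_id}\t{v.verdict}\t{int(v.stop_codon_present)}\t"
                    f"{','.join(sorted(v.warnings)) or '.'}\t"
                    f"{','.join(v.flags) or '.'}\t"
                    f"{'; '.join(v.rationale) or '.'}\n"
                )
    if json_path is not None:
        payload = [
            {
                "group": v.group_id,
                "verdict": v.verdict,
                "stop_codon_present": v.stop_codon_present,
                "warnings": sorted(v.warnings),
                "flags": v.flags,
                "rationale": v.rationale,
            }
            for v in verdicts
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
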