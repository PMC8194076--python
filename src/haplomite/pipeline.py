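"""End-to-end pipeline: trim, collapse, diversity, network, assignment,
codon-position diagnostics and NUMT screening, with file-based inputs and
provenance-stamped outputs.

The pipeline is a pure function of (inputs, configuration, seed): two runs
over the same inputs produce byte-identical output bodies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .diversity import DiversityStats, classify_farm_profile, diversity_stats, \
    write_diversity_tsv
from .haplogroups import Assignment, ReferencePanel, assign, p_distance, \
    write_assignments_tsv
from .haplonet import msn_from_table, star_score
from .numt_screen import (
    NumtVerdict,
    ScreenConfig,
    W1,
    W2,
    W3,
    W4,
    warning_w1,
    warning_w2,
    warning_w3,
    warning_w4,
    warning_w5_and_verdict,
    write_verdicts,
)
from .phylo_diag import resolution_retention, write_retention_tsv
from .seq_core import AlignedMatrix, HaplotypeTable, collapse_haplotypes, \
    trim_to_common_window

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "screen_dataset",
           "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    fasta: str | Path
    sample_sheet: str | Path
    panel_fasta: str | Path
    panel_labels: str | Path
    outdir: str | Path
    farm_alleles: str | Path | None = None  # farm -> nuclear allele ids (TSV)
    trim_policy: str = "trim_columns"
    min_coverage: float = 1.0
    # curated-alignment convention: internal '-' is real indel variation,
    # only N marks absent data for the trimming stage
    trim_gap_is_missing: bool = False
    ambiguity_policy: str = "exclude"
    # gaps kept by default so frameshift-indel haplotypes reach screening
    gap_policy: str = "keep"
    tau_assign: float = 0.03
    bootstrap: int = 100
    model: str = "p"
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def sha(self) -> str:
        payload = {
            k: str(v)
            for k, v in dataclasses.asdict(self).items()
            if k != "outdir"  # analysis parameters only, not output location
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class CandidateGroup:
    group_id: str
    farm: str
    label: str  # assigned label or "X" for unassigned
    hap_ids: list[str]
    divergent: bool


@dataclass
class PipelineResult:
    table: HaplotypeTable
    assignments: dict[str, Assignment]
    farm_stats: dict[str, DiversityStats]
    farm_profiles: dict[str, str]
    verdicts: list[NumtVerdict]
    retention: list
    outputs: dict[str, Path] = field(default_factory=dict)


def _group_seed(seed: int, group_id: str) -> int:
    return (seed * 1000003 + zlib.crc32(group_id.encode())) % (2**31 - 1)


def screen_dataset(
    aln: AlignedMatrix,
    panel: ReferencePanel,
    farm_alleles: dict[str, list[str]] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage on an in-memory aligned dataset."""
    if config is None:
        config = PipelineConfig("", "", "", "", "")
    scfg = config.screen

    missing = frozenset({"-", "N"}) if config.trim_gap_is_missing else frozenset({"N"})
    trimmed, trim_report = trim_to_common_window(
        aln, config.trim_policy, config.min_coverage, missing=missing
    )
    table = collapse_haplotypes(
        trimmed,
        ambiguity_policy=config.ambiguity_policy,
        gap_policy=config.gap_policy,
    )
    # restrict panel references to the analysis window (the panel is
    # assumed aligned to the input's coordinate system)
    start, stop = trim_report.window
    panel = ReferencePanel(
        {rid: seq[start:stop] for rid, seq in panel.references.items()},
        dict(panel.labels),
        dict(panel.statuses),
    )
    hap_seqs = {h.id: h.sequence for h in table.haplotypes}
    assignments = assign(hap_seqs, panel, config.tau_assign)

    # per-sequence calls (for farm profiles): member id -> call
    id_farm = {r.id: r.farm or "?" for r in trimmed.records}
    seq_calls: dict[str, dict[str, str]] = {}
    for h in table.haplotypes:
        call = assignments[h.id].call
        for member in h.members:
            seq_calls.setdefault(id_farm[member], {})[member] = call

    farms = sorted({r.farm or "?" for r in trimmed.records})
    farm_stats: dict[str, DiversityStats] = {}
    farm_profiles: dict[str, str] = {}
    for farm in farms:
        try:
            stats = diversity_stats(table, farm)
        except ValueError:
            continue
        profile, _ = classify_farm_profile(seq_calls.get(farm, {}), stats)
        farm_stats[farm] = stats
        farm_profiles[farm] = profile

    # candidate groups: haplotypes of one assigned label within one farm
    typical_refs = {
        rid: seq
        for rid, seq in panel.references.items()
        if panel.statuses.get(panel.labels[rid]) == "typical"
    }
    outgroup_refs = {
        rid: seq
        for rid, seq in panel.references.items()
        if panel.statuses.get(panel.labels[rid]) == "outgroup"
    }
    groups: list[CandidateGroup] = []
    for farm in farms:
        by_label: dict[str, list[str]] = {}
        for h in table.haplotypes:
            if h.counts.get(farm, 0) == 0:
                continue
            call = assignments[h.id].call
            label = "X" if call == "atypical_unassigned" else call.split("_", 1)[1]
            by_label.setdefault(label, []).append(h.id)
        for label in sorted(by_label):
            hap_ids = sorted(by_label[label])
            div = all(
                min(p_distance(hap_seqs[hid], ref) for ref in typical_refs.values())
                > config.tau_assign
                for hid in hap_ids
            )
            groups.append(CandidateGroup(f"{farm}:{label}", farm, label, hap_ids, div))

    # nuclear allele sharing baseline: alleles seen in farms carrying
    # typical haplotypes
    typical_alleles: set[str] = set()
    if farm_alleles:
        for farm, calls in seq_calls.items():
            if any(c.startswith("typical_") for c in calls.values()):
                typical_alleles.update(farm_alleles.get(farm, []))

    verdicts: list[NumtVerdict] = []
    retention_rows = []
    for grp in groups:
        group_seqs = [hap_seqs[h] for h in grp.hap_ids]
        tree_ids = (
            list(grp.hap_ids) + sorted(typical_refs) + sorted(outgroup_refs)
        )
        extra_refs = {
            rid: seq
            for rid, seq in panel.references.items()
            if panel.statuses.get(panel.labels[rid]) == "cryptic"
            and rid not in grp.hap_ids
        }
        tree_ids += sorted(extra_refs)
        tree_seqs = [
            hap_seqs.get(t) or typical_refs.get(t) or outgroup_refs.get(t)
            or extra_refs.get(t)
            for t in tree_ids
        ]
        rows = resolution_retention(
            tree_ids,
            tree_seqs,
            {grp.group_id: set(grp.hap_ids)},
            frame_offset=scfg.frame_offset,
            bootstrap=config.bootstrap,
            seed=_group_seed(config.seed, grp.group_id),
            model=config.model,
            tau_support=scfg.tau_support,
            tau_stem=scfg.tau_stem,
            min_stem_pos1=scfg.min_stem_pos1,
        )
        retention = rows[0]
        retention_rows.append(retention)
        # W2 needs the all-positions tree; rebuild cheaply without bootstrap
        from .phylo_diag import build_tree

        tree_all = build_tree(tree_ids, tree_seqs, config.model, 0)
        w2, _note = warning_w2(
            tree_all, set(grp.hap_ids), set(typical_refs), set(outgroup_refs)
        )
        w1, stops, _n_aa = warning_w1(
            group_seqs, list(typical_refs.values()), retention, scfg
        )
        sub = table.restrict(grp.farm)
        sub_haps = [h for h in sub.haplotypes if h.id in set(grp.hap_ids)]
        n_grp = sum(h.counts.get(grp.farm, 0) for h in sub_haps)
        if n_grp >= 2:
            grp_table = HaplotypeTable(sub_haps, [], sub.window)
            hd = diversity_stats(grp_table, grp.farm).Hd
            star, _hub = star_score(grp_table, grp.farm)
            w3, _low_n = warning_w3(hd, star, n_grp, scfg)
        else:
            w3 = False
        raw = [r.residues for r in trimmed.records if (r.farm or "?") == grp.farm]
        w4 = warning_w4(raw, scfg)

        nuclear_shared: bool | None = None
        if farm_alleles:
            own = set(farm_alleles.get(grp.farm, []))
            if own:
                nuclear_shared = bool(own & typical_alleles)

        verdicts.append(
            warning_w5_and_verdict(
                grp.group_id,
                {W1: w1, W2: w2, W3: w3, W4: w4},
                stops,
                grp.divergent,
                nuclear_shared,
                scfg,
            )
        )

    return PipelineResult(
        table, assignments, farm_stats, farm_profiles, verdicts, retention_rows
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run; writes every module's output under
    ``config.outdir`` with a provenance header."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        aln = AlignedMatrix.from_fasta(config.fasta, config.sample_sheet)
    except Exception as exc:  # noqa: BLE001 - wrap with stage context
        raise PipelineError("read", str(exc)) from exc
    from .seq_core import read_sample_sheet

    sheet = read_sample_sheet(config.sample_sheet)
    missing = [r.id for r in aln.records if r.id not in sheet]
    if missing:
        raise PipelineError("validate", f"ids missing from sample sheet: {missing[:5]}")

    try:
        panel = ReferencePanel.from_files(config.panel_fasta, config.panel_labels)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("panel", str(exc)) from exc

    farm_alleles: dict[str, list[str]] | None = None
    if config.farm_alleles:
        farm_alleles = {}
        with open(config.farm_alleles) as fh:
            header = fh.readline()
            for line in fh:
                farm, alleles = line.rstrip("\n").split("\t")
                farm_alleles[farm] = alleles.split(",") if alleles else []

    result = screen_dataset(aln, panel, farm_alleles, config)

    prov = [f"haplomite v{__version__}", f"seed={config.seed}",
            f"config_sha={config.sha()}"]
    paths = {
        "haplotypes": outdir / "haplotypes.tsv",
        "diversity": outdir / "diversity.tsv",
        "assignments": outdir / "assignments.tsv",
        "retention": outdir / "retention.tsv",
        "verdicts_tsv": outdir / "verdicts.tsv",
        "verdicts_json": outdir / "verdicts.json",
        "network_gml": outdir / "network.gml",
        "network_nexus": outdir / "network.nex",
        "summary": outdir / "summary.tsv",
    }
    result.table.to_tsv(paths["haplotypes"], prov)
    write_diversity_tsv(
        [result.farm_stats[f] for f in sorted(result.farm_stats)],
        paths["diversity"], prov,
    )
    write_assignments_tsv(result.assignments, paths["assignments"], prov)
    write_retention_tsv(result.retention, paths["retention"], prov)
    write_verdicts(result.verdicts, paths["verdicts_tsv"], paths["verdicts_json"],
                   prov)
    if len(result.table.haplotypes) >= 1:
        net = msn_from_table(result.table)
        net.to_gml(paths["network_gml"])
        net.to_nexus_network(
            paths["network_nexus"],
            {h.id: h.sequence for h in result.table.haplotypes},
        )
    with open(paths["summary"], "w") as fh:
        for line in prov:
            fh.write(f"# {line}\n")
        fh.write("farm\tn\th\tS\tHd\tS_over_h\tprofile\tverdicts\n")
        for farm in sorted(result.farm_stats):
            s = result.farm_stats[farm]
            vs = ";".join(
                f"{v.group_id.split(':', 1)[1]}={v.verdict}"
                for v in result.verdicts
                if v.group_id.startswith(f"{farm}:")
            )
            fh.write(
                f"{farm}\t{s.n}\t{s.h}\t{s.S}\t{s.Hd:.6f}\t{s.S_over_h:.6f}\t"
                f"{result.farm_profiles.get(farm, '.')}\t{vs or '.'}\n"
            )
    result.outputs = paths
    return result
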