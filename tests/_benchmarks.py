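"""Shared seeded benchmarks used by the diagnostic and acceptance tests."""

import numpy as np

from haplomite.haplogroups import ReferencePanel
from haplomite.phylo_diag import resolution_retention
from haplomite.pipeline import PipelineConfig, screen_dataset
from haplomite.seq_core import AlignedMatrix
from haplomite.synthetic_data import (
    SynthConfig,
    simulate_farm_sample,
    simulate_haplogroup_panel,
    simulate_study,
)


def replicate_retention_rows(seeds, bootstrap=100):
    """Retention rows for replicate synthetic panels: typical star groups
    A/B/C(/D) plus one NUMT group 'X' per panel, with outgroups."""
    rows = []
    for seed in seeds:
        cfg = SynthConfig(seed=seed, farm_size=8)
        panel = simulate_haplogroup_panel(cfg)
        rng = np.random.default_rng(10_000 + seed)
        ids, seqs, groups = [], [], {}
        for label in panel.centroids:
            fs = simulate_farm_sample(
                cfg, panel, "single_group", farm_id=label, rng=rng, group=label
            )
            uniq = sorted(set(r.residues for r in fs.records))[:3]
            names = [f"{label}{k}" for k in range(len(uniq))]
            ids += names
            seqs += uniq
            groups[label] = set(names)
        fs = simulate_farm_sample(cfg, panel, "with_numt", farm_id="nf", rng=rng)
        numt = sorted(
            {
                r.residues
                for r, t in zip(fs.records, fs.truth)
                if t["lineage_class"] == "numt"
            }
        )
        names = [f"X{k}" for k in range(len(numt))]
        ids += names
        seqs += numt
        groups["X"] = set(names)
        ids += list(panel.outgroups)
        seqs += list(panel.outgroups.values())
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        rows += resolution_retention(
            ids, seqs, groups, bootstrap=bootstrap, seed=seed
        )
    return rows


def classifier_benchmark(n_studies=13, bootstrap=50, base_seed=0):
    """Screen replicate synthetic studies; tally verdicts by true class.

    Returns (tally, frameshift_results) where tally maps
    (true_class, verdict) -> count over candidate groups and
    frameshift_results lists the verdicts of groups whose NUMT lineage
    carries an in-frame stop.
    """
    tally: dict[tuple[str, str], int] = {}
    frameshift_verdicts = []
    for k in range(n_studies):
        cfg = SynthConfig(seed=base_seed + k, n_haplogroups=4)
        study = simulate_study(
            cfg,
            {"single_group": 1, "mixed_with_C": 1, "with_numt": 4},
            include_cryptic_farms=4,
        )
        aln = AlignedMatrix(study.co1_records)
        panel = ReferencePanel.from_synth(study.panel)
        pcfg = PipelineConfig(
            "", "", "", "", "", bootstrap=bootstrap, seed=base_seed + k
        )
        res = screen_dataset(aln, panel, study.farm_tpm_alleles, pcfg)
        has_stops = {
            farm: any(
                "-" in r
                for r in study.co1_truth.query(
                    "farm == @farm and lineage_class == 'numt'"
                ).seq_id.map(
                    dict((rec.id, rec.residues) for rec in study.co1_records)
                )
            )
            for farm in {f.farm_id for f in study.farms}
        }
        for v in res.verdicts:
            farm, label = v.group_id.split(":", 1)
            if label == "X":
                true = "numt"
                if has_stops.get(farm):
                    frameshift_verdicts.append(v.verdict)
            elif label == "D":
                true = "cryptic"
            else:
                true = "typical"
            tally[(true, v.verdict)] = tally.get((true, v.verdict), 0) + 1
    return tally, frameshift_verdicts


def sensitivity_specificity(tally):
    """numt_suspect vs typical, from a (true class, verdict) tally."""
    tp = tally.get(("numt", "numt_suspect"), 0)
    fn = sum(v for (c, verd), v in tally.items()
             if c == "numt" and verd != "numt_suspect")
    tn = tally.get(("typical", "typical"), 0)
    fp = sum(v for (c, verd), v in tally.items()
             if c == "typical" and verd == "numt_suspect")
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec
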