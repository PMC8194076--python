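"""Synthetic CO1-like and Tpm-like datasets with ground truth.

The generator emulates the population-genetic structure the analysis stages
assume, so every stage is testable without any sequence download:

* three (optionally four) deeply diverged functional haplogroup centroids
  whose substitutions fall on codon position 3 with high probability and
  never create a stop codon;
* farm samples with star-expansion demography — one dominant central
  haplotype surrounded by rare satellites one or two mutations away;
* NUMT pseudogene lineages that evolve position-uniformly from a deep
  (genus-level) ancestral haplotype, optionally carrying a frameshifting
  indel that guarantees downstream in-frame stops, with balanced copy
  frequencies within a farm, and optionally co-amplified with the true
  mitochondrial haplotype as an ambiguity-code consensus;
* nuclear intron allele pools with fixed 3-7 bp indels, heterozygotes
  emitted as the position-wise IUPAC overlay of their two alleles.

Every emitted sequence carries one row in a truth table (lineage class,
haplogroup label, farm, and for Tpm heterozygotes the two true alleles and
the indel), enabling parameter-recovery tests downstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seq_core import (
    GAP,
    AlignedMatrix,
    GeneticCode,
    SequenceRecord,
    iupac_overlay,
    translate,
    write_sample_sheet,
)

__all__ = [
    "SynthConfig",
    "HaplogroupPanel",
    "FarmSample",
    "TpmAllele",
    "TpmDataset",
    "StudyData",
    "SimulationError",
    "simulate_haplogroup_panel",
    "simulate_farm_sample",
    "simulate_tpm_dataset",
    "simulate_study",
    "write_dataset",
]

BASES = "ACGT"
PROFILES = ("single_group", "mixed_with_C", "with_numt")

# depth of the synthetic genealogy, as p-distance increments from the
# genus-level root: species stem, outgroup stem, the two outgroup tips, and
# the ancient NUMT integration (which branches inside the outgroup
# radiation).  Chosen so NUMTs sit well beyond intraspecific divergence from
# every ingroup reference while typical haplogroups stay within
# `intergroup_divergence` of each other.
SPECIES_STEM_DIV = 0.04
OUTGROUP_STEM_DIV = 0.04
OUTGROUP_TIP_DIV = (0.06, 0.08)
NUMT_DIV = 0.08


class SimulationError(RuntimeError):
    """Raised when a constrained placement cannot be satisfied."""


# purifying selection: when a third-position substitution has a synonymous
# alternative, functional lineages take it with this probability
SYNONYMOUS_PREFERENCE = 0.95


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the study conditions emulated."""

    seed: int = 0
    cds_length_bp: int = 471  # 157 codons, frame 0 by construction
    n_haplogroups: int = 3  # A, B, C (+ cryptic D when 4)
    intergroup_divergence: float = 0.05
    third_position_bias: float = 0.9  # q3
    farm_size: int = 20
    star_mutations: tuple[int, ...] = (1, 2)
    satellite_fraction: float = 0.15
    numt_rate: float = 0.3
    numt_indel_prob: float = 0.5
    numt_fraction: float = 0.4  # share of a with_numt farm amplifying the NUMT
    tpm_length_bp: int = 350
    tpm_allele_pool: int = 6
    tpm_indel_lengths: tuple[int, ...] = (3, 4, 5, 6, 7)
    tpm_heterozygotes: int = 12
    genetic_code: int = 5
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.cds_length_bp % 3 != 0 or self.cds_length_bp < 30:
            raise ValueError("cds_length_bp must be a multiple of 3 (>= 30)")
        if not (0 <= self.third_position_bias <= 1):
            raise ValueError("third_position_bias must be in [0, 1]")
        if not (0 < self.intergroup_divergence <= 0.15):
            raise ValueError("intergroup_divergence must be in (0, 0.15]")
        if not (2 <= self.n_haplogroups <= 4):
            raise ValueError("n_haplogroups must be 2..4")
        if self.farm_size < 2:
            raise ValueError("farm_size must be >= 2")
        if not set(self.tpm_indel_lengths) <= set(range(3, 8)):
            raise ValueError("tpm_indel_lengths must be a subset of {3..7}")
        if not self.star_mutations or not set(self.star_mutations) <= {1, 2}:
            raise ValueError("star_mutations support must be within {1, 2}")

    def to_flat(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    def sha(self) -> str:
        return hashlib.sha256(self.to_flat().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# mutation machinery
# ---------------------------------------------------------------------------


def random_cds(length: int, rng: np.random.Generator, code: GeneticCode) -> str:
    """Random in-frame CDS with no stop codon (frame 0)."""
    non_stop = sorted(
        c for c in (a + b + d for a in BASES for b in BASES for d in BASES)
        if not code.is_stop(c)
    )
    idx = rng.integers(0, len(non_stop), size=length // 3)
    return "".join(non_stop[i] for i in idx)


def _codon_position(site: int) -> int:
    return site % 3 + 1  # frame 0 by construction


def mutate_functional(
    seq: str,
    n_mut: int,
    q3: float,
    rng: np.random.Generator,
    code: GeneticCode,
    avoid_sites: set[int] | None = None,
    max_retries: int = 200,
) -> tuple[str, list[int]]:
    """Substitute ``n_mut`` sites under a functional-evolution model:
    third-position bias ``q3``, never creating a stop codon, and preferring
    synonymous alternatives when available (purifying selection).  Returns
    (sequence, mutated sites)."""
    s = list(seq)
    used: set[int] = set(avoid_sites or ())
    sites: list[int] = []
    L = len(seq)
    pos3 = [i for i in range(L) if _codon_position(i) == 3]
    pos12 = [i for i in range(L) if _codon_position(i) != 3]
    for _ in range(n_mut):
        placed = False
        for _try in range(max_retries):
            pool = pos3 if rng.random() < q3 else pos12
            site = pool[rng.integers(0, len(pool))]
            if site in used:
                continue
            old = s[site]
            codon_start = site - site % 3
            old_aa = code.aa("".join(s[codon_start:codon_start + 3]))
            cands, syn = [], []
            for b in BASES:
                if b == old:
                    continue
                codon = s[codon_start:codon_start + 3]
                codon[site - codon_start] = b
                new = "".join(codon)
                if code.is_stop(new):
                    continue
                cands.append(b)
                if code.aa(new) == old_aa:
                    syn.append(b)
            if not cands:
                continue
            if syn and rng.random() < SYNONYMOUS_PREFERENCE:
                cands = syn
            s[site] = cands[rng.integers(0, len(cands))]
            used.add(site)
            sites.append(site)
            placed = True
            break
        if not placed:
            raise SimulationError(
                "could not place a stop-free biased substitution "
                f"(n_mut={n_mut}, q3={q3})"
            )
    return "".join(s), sites


def mutate_uniform(
    seq: str,
    n_mut: int,
    rng: np.random.Generator,
    avoid_sites: set[int] | None = None,
) -> tuple[str, list[int]]:
    """Position-uniform substitutions with no functional constraint."""
    s = list(seq)
    used: set[int] = set(avoid_sites or ())
    candidates = [i for i in range(len(seq)) if i not in used]
    if n_mut > len(candidates):
        raise SimulationError("more mutations requested than free sites")
    chosen = rng.choice(len(candidates), size=n_mut, replace=False)
    sites = sorted(candidates[int(i)] for i in chosen)
    for site in sites:
        alts = [b for b in BASES if b != s[site]]
        s[site] = alts[rng.integers(0, 3)]
    return "".join(s), sites


# ---------------------------------------------------------------------------
# haplogroup panel
# ---------------------------------------------------------------------------


@dataclass
class HaplogroupPanel:
    """Centroid sequences per haplogroup plus the synthetic genealogy around
    them (genus root, species ancestor, outgroups, NUMT centroid)."""

    root: str
    ancestor: str
    centroids: dict[str, str]
    outgroups: dict[str, str]
    numt_centroid: str
    numt_source: str  # the ancestral haplotype the NUMT was copied from
    config: SynthConfig

    @property
    def labels(self) -> list[str]:
        return list(self.centroids)


def simulate_haplogroup_panel(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> HaplogroupPanel:
    """Generate one stop-free centroid per haplogroup around a shared
    species ancestor, plus outgroups and an ancient NUMT centroid.

    Centroid pairwise p-distances equal ``intergroup_divergence`` (to
    rounding): each centroid receives half the target number of
    substitutions on sites disjoint from every other centroid's.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    code = GeneticCode(config.genetic_code)
    L = config.cds_length_bp
    q3 = config.third_position_bias

    root = random_cds(L, rng, code)
    ancestor, anc_sites = mutate_functional(
        root, round(SPECIES_STEM_DIV * L), q3, rng, code
    )
    og_anc, og_sites = mutate_functional(
        root, round(OUTGROUP_STEM_DIV * L), q3, rng, code
    )
    # OG1 sits at the end of a two-step stem; the NUMT centroid branches off
    # halfway along it, so an ancient pseudogene lineage genuinely falls
    # inside the congeneric outgroup radiation (the placement reported for
    # deep NUMT haplogroups), then evolves position-uniformly.
    og1_mid, _ = mutate_functional(og_anc, round(OUTGROUP_TIP_DIV[0] / 2 * L),
                                   q3, rng, code)
    og1, _ = mutate_functional(og1_mid, round(OUTGROUP_TIP_DIV[0] / 2 * L),
                               q3, rng, code)
    og2, _ = mutate_functional(og_anc, round(OUTGROUP_TIP_DIV[1] * L),
                               q3, rng, code)
    outgroups = {"OG1": og1, "OG2": og2}

    labels = ["A", "B", "C", "D"][: config.n_haplogroups]
    per_centroid = max(1, round(config.intergroup_divergence * L / 2))
    centroids: dict[str, str] = {}
    used: set[int] = set()
    for label in labels:
        seq, sites = mutate_functional(
            ancestor, per_centroid, q3, rng, code, avoid_sites=used
        )
        used.update(sites)
        centroids[label] = seq

    numt_centroid, _ = mutate_uniform(og1_mid, round(NUMT_DIV * L), rng)

    target = config.intergroup_divergence
    for a in labels:
        for b in labels:
            if a < b:
                d = _hamming(centroids[a], centroids[b]) / L
                if not (0.8 * target <= d <= 1.2 * target):
                    raise SimulationError(
                        f"centroid divergence {d:.4f} outside {target} +/- 20%"
                    )
    return HaplogroupPanel(
        root, ancestor, centroids, outgroups, numt_centroid, og1_mid, config
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# farm samples
# ---------------------------------------------------------------------------


@dataclass
class FarmSample:
    farm_id: str
    profile: str
    records: list[SequenceRecord]
    truth: list[dict] = field(default_factory=list)


def _distinct_satellite(
    hub: str,
    existing: set[str],
    k_choices: Sequence[int],
    q3: float,
    rng: np.random.Generator,
    code: GeneticCode,
    uniform: bool = False,
    avoid_sites: set[int] | None = None,
) -> str:
    for _ in range(100):
        k = int(k_choices[rng.integers(0, len(k_choices))])
        if uniform:
            sat, _ = mutate_uniform(hub, k, rng, avoid_sites=avoid_sites)
        else:
            sat, _ = mutate_functional(hub, k, q3, rng, code)
        if sat not in existing:
            return sat
    raise SimulationError("could not generate a distinct satellite haplotype")


def _star_sequences(
    hub: str,
    n: int,
    config: SynthConfig,
    rng: np.random.Generator,
    code: GeneticCode,
) -> list[str]:
    """Hub copies plus Poisson-thin satellites at 1-2 mutations (sampled
    directly as the resulting pattern, not via explicit coalescent)."""
    n_sat = int(rng.binomial(n - 1, config.satellite_fraction))
    sats: set[str] = set()
    while len(sats) < n_sat:
        sats.add(
            _distinct_satellite(
                hub, sats | {hub}, config.star_mutations,
                config.third_position_bias, rng, code,
            )
        )
    return [hub] * (n - n_sat) + sorted(sats)


def _frameshift_numt(
    founder: str,
    rng: np.random.Generator,
    code: GeneticCode,
    frame_offset: int = 0,
) -> tuple[str, int]:
    """Delete one base (kept as an aligned '-') so that the translation has
    at least one in-frame stop downstream of the indel."""
    L = len(founder)
    for _ in range(200):
        pos = int(rng.integers(L // 4, 3 * L // 4))
        shifted = founder[:pos] + GAP + founder[pos + 1 :]
        _, stops = translate(shifted, code, frame_offset)
        if any(s >= pos // 3 for s in stops):
            return shifted, pos
    raise SimulationError("no frameshift position yields a downstream stop")


def simulate_farm_sample(
    config: SynthConfig,
    panel: HaplogroupPanel,
    profile: str,
    farm_id: str = "farm1",
    rng: np.random.Generator | None = None,
    group: str | None = None,
    coamplified: bool = False,
    country: str = "XX",
) -> FarmSample:
    """Sample one farm under a demographic profile.

    ``single_group``: one star (dominant central haplotype + rare satellites).
    ``mixed_with_C``: two or three stars from distinct typical haplogroups,
    always including C. ``with_numt``: a typical star plus a NUMT lineage at
    balanced copy frequencies, optionally co-amplified (emitted as the IUPAC
    overlay of mitochondrial and NUMT templates).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    if config.farm_size < 2:
        raise ValueError("farm_size must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    code = GeneticCode(config.genetic_code)
    n = config.farm_size
    labels = panel.labels
    typical = [l for l in labels if l != "D"]

    entries: list[tuple[str, str, str]] = []  # (sequence, lineage_class, label)

    def star_for(label: str, count: int) -> None:
        hub, _ = mutate_functional(
            panel.centroids[label], int(rng.integers(0, 3)),
            config.third_position_bias, rng, code,
        )
        cls = "cryptic" if label == "D" else "typical"
        for seq in _star_sequences(hub, count, config, rng, code):
            entries.append((seq, cls, label))

    if profile == "single_group":
        # the cryptic lineage (D) is sampled only when explicitly requested
        label = group or typical[rng.integers(0, len(typical))]
        if label not in panel.centroids:
            raise ValueError(f"unknown haplogroup {label!r}")
        star_for(label, n)

    elif profile == "mixed_with_C":
        if "C" not in panel.centroids:
            raise ValueError("panel lacks haplogroup C")
        if n < 6:
            raise ValueError("mixed_with_C needs farm_size >= 6 (>=3 per star)")
        k = min(int(rng.integers(2, 4)), n // 3)
        others = [l for l in typical if l != "C"]
        pick = list(rng.choice(others, size=min(k - 1, len(others)), replace=False))
        groups = ["C"] + [str(g) for g in pick]
        base = [3] * len(groups)
        extra = rng.multinomial(n - sum(base), [1 / len(groups)] * len(groups))
        for g, b, e in zip(groups, base, extra):
            star_for(g, b + int(e))

    elif profile == "with_numt":
        m = max(4, round(config.numt_fraction * n))
        label = group or typical[rng.integers(0, len(typical))]
        star_for(label, n - m)
        founder, _ = mutate_uniform(panel.numt_centroid, int(rng.integers(2, 5)), rng)
        indel_pos = None
        if rng.random() < config.numt_indel_prob:
            founder, indel_pos = _frameshift_numt(founder, rng, code, config.frame_offset)
        k_var = int(rng.integers(3, min(6, m) + 1))
        variants = [founder]
        avoid = {indel_pos} if indel_pos is not None else set()
        while len(variants) < k_var:
            v = _distinct_satellite(
                founder, set(variants), (1, 2, 3), 0.0, rng, code,
                uniform=True, avoid_sites=avoid,
            )
            variants.append(v)
        # balanced copy numbers: as-even-as-possible split keeps max/min <= 3
        counts = [m // k_var + (1 if i < m % k_var else 0) for i in range(k_var)]
        mito_hub = entries[0][0]
        for v, c in zip(variants, counts):
            for _ in range(c):
                if coamplified:
                    ungapped = v.replace(GAP, "")
                    cons = iupac_overlay(mito_hub, ungapped)
                    cons = cons + "N" * (len(mito_hub) - len(cons))
                    entries.append((cons, "numt_coamplified", "NUMT"))
                else:
                    entries.append((v, "numt", "NUMT"))

    order = rng.permutation(len(entries))
    records, truth = [], []
    for i, j in enumerate(order):
        seq, cls, label = entries[int(j)]
        sid = f"{farm_id}_s{i + 1:03d}"
        records.append(
            SequenceRecord(sid, seq, farm=farm_id, country=country, marker="CO1_region1")
        )
        truth.append(
            {
                "seq_id": sid,
                "farm": farm_id,
                "lineage_class": cls,
                "haplogroup_label": label,
                "marker": "CO1_region1",
            }
        )
    return FarmSample(farm_id, profile, records, truth)


# ---------------------------------------------------------------------------
# Tpm intron dataset
# ---------------------------------------------------------------------------


@dataclass
class TpmAllele:
    id: str
    sequence: str
    indel: tuple[int, int] | None  # (position, length) relative to the ancestor
    private: bool = False


@dataclass
class TpmDataset:
    pool: list[TpmAllele]
    records: list[SequenceRecord]
    truth: list[dict]

    def allele(self, allele_id: str) -> TpmAllele:
        for a in self.pool:
            if a.id == allele_id:
                return a
        raise KeyError(allele_id)


def _random_intron(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_tpm_allele_pool(
    config: SynthConfig,
    rng: np.random.Generator,
    n_private: int = 2,
) -> list[TpmAllele]:
    """Allele pool: the ancestral intron plus variants carrying fixed-length
    (3-7 bp) deletions in the first third of the intron and private SNPs
    downstream of the indel zone.

    Placing substitutions downstream keeps every inter-allele difference
    within reach of the indel-shift phasing decoder (the phase of variation
    upstream of a heterozygous indel is not determined by a single overlaid
    trace; see docs).  Each indel allele is additionally required to form a
    phase-identifiable overlay with every indel-free allele already in the
    pool: overlay coincidences that genuinely underdetermine the allele
    pair (resolvable in practice only against a homozygote catalog) are
    re-drawn.
    """
    from .phasing import overlay_is_identifiable

    if config.tpm_allele_pool < 1:
        raise ValueError("empty allele pool requested")
    Lb = config.tpm_length_bp
    ancestor = _random_intron(Lb, rng)
    indel_zone = (20, Lb // 3)
    snp_zone_start = Lb // 3 + max(config.tpm_indel_lengths) + 1

    pool: list[TpmAllele] = [TpmAllele("Tro1", ancestor, None)]
    seen = {ancestor}

    def add_allele(name: str, with_indel: bool, private: bool) -> None:
        for _ in range(100):
            seq = ancestor
            indel = None
            if with_indel:
                L = int(
                    config.tpm_indel_lengths[
                        rng.integers(0, len(config.tpm_indel_lengths))
                    ]
                )
                p = int(rng.integers(*indel_zone))
                seq = seq[:p] + seq[p + L :]
                indel = (p, L)
            n_snp = int(rng.integers(1, 4)) + (2 if private else 0)
            s = list(seq)
            offset = indel[1] if indel else 0
            lo = snp_zone_start - offset
            sites = rng.choice(len(s) - lo - 5, size=n_snp, replace=False) + lo
            for site in sites:
                alts = [b for b in BASES if b != s[site]]
                s[site] = alts[rng.integers(0, 3)]
            seq = "".join(s)
            if seq in seen:
                continue
            # an indel allele must form a phase-identifiable overlay with at
            # least one indel-free allele, so heterozygotes carrying it are
            # decodable; overlay coincidences are re-drawn
            if indel is not None:
                partners = [a for a in pool if a.indel is None]
                if partners and not any(
                    overlay_is_identifiable(a.sequence, seq, indel)
                    for a in partners
                ):
                    continue
            seen.add(seq)
            pool.append(TpmAllele(name, seq, indel, private))
            return
        raise SimulationError("could not generate a distinct Tpm allele")

    for i in range(2, config.tpm_allele_pool + 1):
        add_allele(f"Tro{i}", with_indel=bool(rng.random() < 0.6), private=False)
    for i in range(1, n_private + 1):
        add_allele(f"Prv{i}", with_indel=bool(rng.random() < 0.6), private=True)
    return pool


def _het_consensus(a: TpmAllele, b: TpmAllele) -> str:
    longer, shorter = (a, b) if len(a.sequence) >= len(b.sequence) else (b, a)
    return iupac_overlay(longer.sequence, shorter.sequence)


def simulate_tpm_dataset(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    farm_id: str = "tpm",
    pool: list[TpmAllele] | None = None,
    allowed: list[str] | None = None,
) -> TpmDataset:
    """Emit homozygote alleles plus heterozygote IUPAC consensus sequences.

    Heterozygote pairs differ by at most one fixed-length indel (one allele
    with, one without); indel heterozygotes are drawn only from
    phase-identifiable pairs, matching field samples where the remainder
    must be resolved by catalog comparison or resequencing."""
    from .phasing import overlay_is_identifiable

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if pool is None:
        pool = simulate_tpm_allele_pool(config, rng, n_private=0)
    use = [a for a in pool if allowed is None or a.id in allowed]
    if not use:
        raise SimulationError("empty allele pool")
    no_indel = [a for a in use if a.indel is None]
    with_indel = [a for a in use if a.indel is not None]
    indel_pairs = [
        (a, b)
        for a in no_indel
        for b in with_indel
        if overlay_is_identifiable(a.sequence, b.sequence, b.indel)
    ]

    records: list[SequenceRecord] = []
    truth: list[dict] = []

    def emit(seq: str, zyg: str, a1: TpmAllele, a2: TpmAllele) -> None:
        sid = f"{farm_id}_t{len(records) + 1:03d}"
        records.append(SequenceRecord(sid, seq, farm=farm_id, marker="Tpm"))
        longer, shorter = (a1, a2) if len(a1.sequence) >= len(a2.sequence) else (a2, a1)
        indel = shorter.indel if len(a1.sequence) != len(a2.sequence) else None
        truth.append(
            {
                "seq_id": sid,
                "farm": farm_id,
                "zygosity": zyg,
                "allele_1": longer.id,
                "allele_2": shorter.id,
                "allele_1_seq": longer.sequence,
                "allele_2_seq": shorter.sequence,
                "indel_pos": indel[0] if indel else -1,
                "indel_len": indel[1] if indel else 0,
                "marker": "Tpm",
            }
        )

    for a in use:
        emit(a.sequence, "hom", a, a)
    for _ in range(config.tpm_heterozygotes):
        if indel_pairs and rng.random() < 0.8:
            a1, a2 = indel_pairs[rng.integers(0, len(indel_pairs))]
        elif len(no_indel) >= 2:
            i, j = rng.choice(len(no_indel), size=2, replace=False)
            a1, a2 = no_indel[int(i)], no_indel[int(j)]
        else:
            a1 = a2 = use[rng.integers(0, len(use))]
        emit(_het_consensus(a1, a2), "het" if a1.id != a2.id else "hom", a1, a2)
    return TpmDataset(pool, records, truth)


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    panel: HaplogroupPanel
    farms: list[FarmSample]
    co1_records: list[SequenceRecord]
    co1_truth: pd.DataFrame
    tpm: TpmDataset
    farm_tpm_alleles: dict[str, list[str]]
    config: SynthConfig


def simulate_study(
    config: SynthConfig,
    profile_counts: dict[str, int] | None = None,
    coamplified_numt: bool = False,
    include_cryptic_farms: int = 0,
) -> StudyData:
    """Simulate a multi-farm study: a haplogroup panel, farms under the
    requested profile mix, and a farm-linked Tpm allele table.

    Cryptic farms (haplogroup D stars carrying private nuclear alleles)
    require ``n_haplogroups=4``.
    """
    rng = np.random.default_rng(config.seed)
    if profile_counts is None:
        profile_counts = {"single_group": 3, "mixed_with_C": 2, "with_numt": 2}
    panel = simulate_haplogroup_panel(config, rng)
    if include_cryptic_farms and "D" not in panel.centroids:
        raise ValueError("cryptic farms require n_haplogroups=4")

    pool = simulate_tpm_allele_pool(config, rng, n_private=2 if include_cryptic_farms else 0)
    shared_ids = [a.id for a in pool if not a.private]
    private_ids = [a.id for a in pool if a.private]

    farms: list[FarmSample] = []
    records: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    farm_alleles: dict[str, list[str]] = {}
    tpm_records: list[SequenceRecord] = []
    tpm_truth: list[dict] = []

    def add_farm(profile: str, idx: int, group: str | None = None) -> None:
        tag = {"single_group": "single", "mixed_with_C": "mixed",
               "with_numt": "numt"}[profile]
        if group == "D":
            tag = "cryptic"
        fid = f"{tag}{idx:02d}"
        fs = simulate_farm_sample(
            config, panel, profile, farm_id=fid, rng=rng, group=group,
            coamplified=coamplified_numt and profile == "with_numt",
        )
        farms.append(fs)
        records.extend(fs.records)
        truth_rows.extend(fs.truth)
        ids = private_ids if group == "D" else shared_ids
        k = min(len(ids), int(rng.integers(2, 4)))
        chosen = sorted(str(x) for x in rng.choice(ids, size=k, replace=False))
        farm_alleles[fid] = chosen
        sub = simulate_tpm_dataset(config, rng, farm_id=fid, pool=pool, allowed=chosen)
        tpm_records.extend(sub.records)
        tpm_truth.extend(sub.truth)

    for profile in PROFILES:
        for i in range(profile_counts.get(profile, 0)):
            add_farm(profile, i + 1)
    for i in range(include_cryptic_farms):
        add_farm("single_group", i + 1, group="D")

    tpm = TpmDataset(pool, tpm_records, tpm_truth)
    truth = pd.DataFrame(truth_rows)
    return StudyData(panel, farms, records, truth, tpm, farm_alleles, config)


def write_dataset(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Write sequences.fasta / tpm.fasta, samples.tsv, truth tables, the
    panel (FASTA + labels TSV) and the flat config. Byte-deterministic for a
    given config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": outdir / "sequences.fasta",
        "tpm": outdir / "tpm.fasta",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "tpm_truth": outdir / "tpm_truth.tsv",
        "panel_fasta": outdir / "panel.fasta",
        "panel_labels": outdir / "panel_labels.tsv",
        "farm_alleles": outdir / "farm_tpm_alleles.tsv",
        "config": outdir / "config.txt",
    }
    AlignedMatrix(study.co1_records).to_fasta(paths["sequences"])
    if study.tpm.records:
        with open(paths["tpm"], "w") as fh:
            for r in study.tpm.records:
                fh.write(f">{r.id}\n")
                for i in range(0, len(r.residues), 60):
                    fh.write(r.residues[i : i + 60] + "\n")
    write_sample_sheet(study.co1_records + study.tpm.records, paths["samples"])
    study.co1_truth.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(study.tpm.truth).to_csv(paths["tpm_truth"], sep="\t", index=False)

    with open(paths["panel_fasta"], "w") as fh, open(paths["panel_labels"], "w") as lf:
        lf.write("id\tlabel\tstatus\n")
        for label, seq in study.panel.centroids.items():
            status = "cryptic" if label == "D" else "typical"
            fh.write(f">ref_{label}\n{seq}\n")
            lf.write(f"ref_{label}\t{label}\t{status}\n")
        for name, seq in study.panel.outgroups.items():
            fh.write(f">{name}\n{seq}\n")
            lf.write(f"{name}\t{name}\toutgroup\n")
    with open(paths["farm_alleles"], "w") as fh:
        fh.write("farm\talleles\n")
        for fid in sorted(study.farm_tpm_alleles):
            fh.write(f"{fid}\t{','.join(study.farm_tpm_alleles[fid])}\n")
    paths["config"].write_text(study.config.to_flat())
    return paths
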