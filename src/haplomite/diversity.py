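"""Per-population haplotype diversity statistics and farm-profile classes.

For each farm (population) the statistics reported are the sample size n,
the number of distinct haplotypes h, the number of segregating sites S in
the analysis window, Nei's small-sample-corrected haplotype diversity

    Hd = n (1 - sum_i p_i^2) / (n - 1),    p_i = count_i / n,

and the ratio S/h, which rises when deeply diverged haplogroups co-occur in
one building even if Hd stays moderate.  Farms are classified into three
mitochondrial profiles: a single typical haplogroup, a mixture of typical
haplogroups including C, or any atypical (unassignable) haplotypes present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_core import GAP, HaplotypeTable

__all__ = ["DiversityStats", "diversity_stats", "classify_farm_profile",
           "write_diversity_tsv"]

PROFILE_SINGLE = "single_typical"
PROFILE_MIXED_C = "mixed_including_C"
PROFILE_ATYPICAL = "atypical_present"


@dataclass
class DiversityStats:
    population: str
    n: int
    h: int
    S: int
    Hd: float
    S_over_h: float
    profile: str | None = None
    flags: list[str] = field(default_factory=list)


def diversity_stats(
    table: HaplotypeTable,
    population: str,
    count_gaps: bool = False,
) -> DiversityStats:
    """Diversity statistics for one population of a haplotype table.

    Segregating sites are counted over the haplotypes present in the
    population; gaps are a fifth state excluded from S unless
    ``count_gaps`` is set.
    """
    haps = [h for h in table.haplotypes if h.counts.get(population, 0) > 0]
    if not haps:
        raise ValueError(f"population {population!r} not present")
    counts = [h.counts[population] for h in haps]
    n = sum(counts)
    if n < 2:
        raise ValueError(f"population {population!r} has n={n} < 2")
    h_num = len(haps)
    sum_p2 = sum((c / n) ** 2 for c in counts)
    hd = n * (1.0 - sum_p2) / (n - 1)

    L = len(haps[0].sequence)
    S = 0
    for col in range(L):
        states = {hap.sequence[col] for hap in haps}
        if not count_gaps:
            states.discard(GAP)
        if len(states) >= 2:
            S += 1
    return DiversityStats(population, n, h_num, S, hd, S / h_num)


def classify_farm_profile(
    calls: dict[str, str],
    stats: DiversityStats | None = None,
) -> tuple[str, list[str]]:
    """Fig.-style mitochondrial profile of a farm from per-sequence
    haplogroup calls (``typical_A`` ... ``cryptic_D`` /
    ``atypical_unassigned``).

    Returns (profile, flags); the ``high_S_over_h`` flag marks the
    mixed-including-C pattern, where high S/h is the expected signature.
    """
    if not calls:
        raise ValueError("missing haplogroup assignments")
    flags: list[str] = []
    atypical = any(c == "atypical_unassigned" for c in calls.values())
    groups = {
        c.split("_", 1)[1]
        for c in calls.values()
        if c.startswith("typical_")
    }
    if atypical:
        profile = PROFILE_ATYPICAL
    elif len(groups) >= 2 and "C" in groups:
        profile = PROFILE_MIXED_C
        flags.append("high_S_over_h")
    else:
        profile = PROFILE_SINGLE
    if stats is not None:
        stats.profile = profile
        stats.flags = list(flags)
    return profile, flags


def write_diversity_tsv(stats: list[DiversityStats], path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("farm\tn\th\tS\tHd\tS_over_h\tprofile\tflags\n")
        for s in stats:
            fh.write(
                f"{s.population}\t{s.n}\t{s.h}\t{s.S}\t{s.Hd:.6f}\t"
                f"{s.S_over_h:.6f}\t{s.profile or '.'}\t"
                f"{','.join(s.flags) or '.'}\n"
            )
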