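"""Separation of the two alleles of a heterozygous intron consensus.

A heterozygous individual sequenced by the Sanger method yields superimposed
double peaks, rendered here as a single consensus string with IUPAC
ambiguity codes.  When the two alleles differ by one fixed-length indel
(3-7 bp indels recur across the intron used for this mite), the indel
offsets one allele against the other downstream of its position: every
consensus position i >= p then shows the union of allele1[i] and
allele1[i+L] (modulo substitutions), and this self-overlap is decodable.

``phase_heterozygote`` scans every (position, length) hypothesis, decodes
the maximum-parsimony allele pair under each, scores the fraction of
ambiguous positions the overlay explains, and returns the best hypothesis.
The phase of substitution differences *upstream* of the indel is not
determined by a single trace (both assignments produce the same overlay);
such cases are returned with low confidence, to be resolved against a
homozygote allele catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_core import AMBIGUITY_SETS, iupac_overlay

__all__ = ["PhasedPair", "PhasingError", "phase_heterozygote",
           "match_against_catalog", "CatalogMatch"]

_UNAMB = frozenset("ACGT")


class PhasingError(RuntimeError):
    """No hypothesis explains enough of the ambiguity signal."""


@dataclass
class PhasedPair:
    allele_1: str  # the longer allele (no gap)
    allele_2: str
    indel: tuple[int, int] | None  # (position, length) on allele_1, or None
    explained_ambiguities: float
    confidence: str  # "high" | "low"
    n_substitutions: int = 0
    notes: list[str] = field(default_factory=list)


def overlay_is_identifiable(
    long_allele: str, short_allele: str, indel: tuple[int, int] | None
) -> bool:
    """Whether the IUPAC overlay of two alleles determines the pair as the
    unique maximum-parsimony decode under the (known) indel hypothesis.

    Pairs failing this — overlay coincidences admitting a tied or more
    parsimonious alternative reading — are the ones a single overlaid trace
    cannot phase; in practice they are resolved against a homozygote allele
    catalog or by resequencing with internal primers.
    """
    consensus = iupac_overlay(long_allele, short_allele)
    S = _base_sets(consensus)
    n_amb = sum(1 for cs in S if len(cs) > 1)
    if n_amb == 0:
        return True
    if indel is None:
        return n_amb <= 1
    decoded = _decode_hypothesis(S, indel[0], indel[1], n_amb)
    return (
        decoded is not None
        and decoded[0] == 1.0
        and not decoded[4]
        and decoded[2] == long_allele
        and decoded[3] == short_allele[: len(consensus)]
    )


def _base_sets(consensus: str) -> list[frozenset[str]]:
    sets = []
    for c in consensus:
        if c not in AMBIGUITY_SETS:
            raise ValueError(f"invalid IUPAC character {c!r}")
        sets.append(AMBIGUITY_SETS[c])
    return sets


def _score_assignment(
    X: list[str], S: list[frozenset[str]], p: int, L: int, n_amb: int
) -> tuple[float, int, str] | None:
    """Given a fully assigned long allele X under hypothesis (p, L), derive
    the short allele, the substitution count and the explained fraction."""
    n = len(S)
    unexplained = 0
    subs = 0
    a2 = list(X[:p])
    for j in range(p):
        if len(S[j]) == 2:
            # upstream heterozygous substitution: overlay explained, phase not
            lo, hi = sorted(S[j])
            a2[j] = hi if X[j] == lo else lo
            subs += 1
        elif len(S[j]) > 2:
            unexplained += 1
    for i in range(p, n):
        si = S[i]
        if len(si) == 1:
            y = X[i] if X[i] in si else None
        elif len(si) == 2 and X[i] in si:
            y = next(iter(si - {X[i]}))
        else:
            y = None
        if y is None:
            unexplained += 1
            y = min(si)
        a2.append(y)
        if y != X[i + L]:
            subs += 1
    explained = 1.0 if n_amb == 0 else 1.0 - unexplained / n_amb
    return explained, subs, "".join(a2)


def _decode_hypothesis(
    S: list[frozenset[str]], p: int, L: int, n_amb: int,
    cost_limit: int | None = None,
) -> tuple[float, int, str, str, bool] | None:
    """Best (explained, n_subs, allele_1, allele_2, ambiguous_decode) for
    hypothesis (p, L).

    Under a deletion of length L at position p of the long allele X, the
    short allele satisfies Y[i] = X[i+L] except at substitution sites, and
    every consensus column i >= p constrains the pair (X[i], X[i+L]) via
    {X[i]} u {Y[i]} = S[i].  Positions of X congruent mod L therefore form
    independent chains, each solved exactly by a Viterbi-style dynamic
    program minimizing the number of implied substitutions.
    """
    n = len(S)
    BASES = "ACGT"
    X: list[str | None] = [None] * (n + L)
    for j in range(p):
        X[j] = min(S[j])  # doubletons are upstream SNPs, phase arbitrary

    # branch-and-bound floor: substitutions implied upstream of the indel
    base_cost = sum(1 for j in range(p) if len(S[j]) == 2)
    if cost_limit is not None and base_cost > cost_limit:
        return None

    ambiguous_decode = False
    for r in range(L):
        chain = list(range(p + r, n + L, L))
        if not chain:
            continue

        def domain(j: int) -> tuple[str, ...]:
            return tuple(sorted(S[j])) if j < n else tuple(BASES)

        def trans_cost(j: int, a: str, b: str) -> int:
            # consensus column j couples X[j]=a with X[j+L]=b via the
            # short allele: Y[j] != b costs one substitution
            sj = S[j]
            if len(sj) == 1:
                y = a
            elif len(sj) == 2:
                y = next(iter(sj - {a})) if a in sj else None
            else:
                y = None  # >2-state column: unexplainable, no constraint
            return 0 if (y is None or y == b) else 1

        # states: base -> (cost, n_optimal_paths, predecessor)
        dp: list[dict[str, tuple[int, int, str | None]]] = [
            {b: (0, 1, None) for b in domain(chain[0])}
        ]
        for k in range(1, len(chain)):
            jprev = chain[k - 1]
            cur: dict[str, tuple[int, int, str | None]] = {}
            for b in domain(chain[k]):
                best_cost, best_a, n_paths = None, None, 0
                for a in sorted(dp[k - 1]):
                    cost_a, cnt_a, _ = dp[k - 1][a]
                    c = cost_a + trans_cost(jprev, a, b)
                    if best_cost is None or c < best_cost:
                        best_cost, best_a, n_paths = c, a, cnt_a
                    elif c == best_cost:
                        n_paths = min(n_paths + cnt_a, 1000)
                if best_cost is not None:
                    cur[b] = (best_cost, n_paths, best_a)
            if not cur:
                return None
            if cost_limit is not None:
                floor = base_cost + min(c for c, _, _ in cur.values())
                if floor > cost_limit:
                    return None
            dp.append(cur)
        last = dp[-1]
        end_cost = min(c for c, _, _ in last.values())
        finals = sorted(b for b, (c, _, _) in last.items() if c == end_cost)
        if sum(last[b][1] for b in finals) > 1:
            ambiguous_decode = True
        b = finals[0]
        for k in range(len(chain) - 1, -1, -1):
            X[chain[k]] = b
            b = dp[k][b][2]
        base_cost += end_cost  # chains accumulate toward the bound

    assert all(x is not None for x in X)
    explained, subs, a2 = _score_assignment(X, S, p, L, n_amb)  # type: ignore[arg-type]
    if any(len(S[j]) == 2 for j in range(p)):
        ambiguous_decode = True  # upstream heterozygous sites: phase arbitrary
    return explained, subs, "".join(X), a2, ambiguous_decode  # type: ignore[arg-type]


def phase_heterozygote(
    consensus: str,
    max_indel: int = 7,
    min_explained: float = 0.9,
) -> PhasedPair:
    """Decode a heterozygote consensus into its two alleles.

    Hypotheses are a single deletion of length 1..``max_indel`` in one
    allele (plus the no-indel, substitutions-only hypothesis); the returned
    pair maximizes explained ambiguity, then parsimony (fewest implied
    substitutions).  Raises :class:`PhasingError` when no hypothesis
    explains more than ``min_explained`` of the ambiguous positions —
    the signature of multi-indel heterozygotes or unusable trace quality.
    """
    consensus = consensus.upper()
    S = _base_sets(consensus)
    n = len(S)
    amb = [i for i, cs in enumerate(S) if len(cs) > 1]
    if not amb:
        return PhasedPair(consensus, consensus, None, 1.0, "high", 0)

    # (explained, subs, allele_1, allele_2, indel, ambiguous_decode)
    results: list[tuple[float, int, str, str, tuple[int, int] | None, bool]] = []

    # no-indel hypothesis: every ambiguous site is a substitution; linkage
    # between >=2 sites is not knowable from one consensus
    if all(len(cs) <= 2 for cs in S):
        a1 = "".join(min(cs) for cs in S)
        a2 = "".join(max(cs) for cs in S)
        results.append((1.0, len(amb), a1, a2, None, len(amb) > 1))

    # the deletion cannot start far after the first ambiguous column (the
    # overlay is ambiguity-free before it, bar upstream substitutions), and
    # starting it earlier than a short repeat-length before is equivalent
    first_amb = amb[0]
    p_lo = max(0, first_amb - 12)
    p_hi = min(n - 1, first_amb + 32)
    # branch-and-bound: a fully-explaining result caps the substitution
    # count any competing hypothesis may spend (its events must not exceed
    # the current best); the no-indel reading provides the initial cap
    limit = len(amb) - 1 if results else None
    # the overlay is ambiguity-free before the deletion (bar upstream
    # substitutions), so p = first_amb is the most likely start: trying it
    # first makes the branch-and-bound cap tight almost immediately
    p_order = list(range(first_amb, p_lo - 1, -1)) + list(
        range(first_amb + 1, p_hi + 1)
    )
    for L in range(1, max_indel + 1):
        for p in p_order:
            decoded = _decode_hypothesis(S, p, L, len(amb), cost_limit=limit)
            if decoded is None:
                continue
            explained, subs, a1, a2, amb_decode = decoded
            results.append((explained, subs, a1, a2, (p, L), amb_decode))
            if explained == 1.0:
                limit = min(limit, subs) if limit is not None else subs

    if not results:
        raise PhasingError("no decodable hypothesis (search space exhausted)")

    # rank by explained ambiguity, then total mutational events (an indel
    # counts as one event, so a lone substitution is not reinterpreted as a
    # deletion), preferring the substitution-only reading on exact ties
    def events(r):
        return r[1] + (0 if r[4] is None else 1)

    results.sort(key=lambda r: (-r[0], events(r), r[4] is not None, r[2], r[3]))
    explained, subs, a1, a2, indel, amb_decode = results[0]
    if explained < min_explained:
        raise PhasingError(
            f"best hypothesis explains only {explained:.0%} of ambiguous sites "
            "(multiple indels or unusable trace?)"
        )
    if indel is not None:
        # ambiguity must be explained by the shift overlay itself, not by an
        # open-ended substitution budget: a second indel or pervasive double
        # peaks shows up as a run of implied substitutions
        overlay_explained = explained - subs / len(amb)
        if overlay_explained < min_explained:
            raise PhasingError(
                f"shift overlay explains only {max(overlay_explained, 0.0):.0%} "
                "of ambiguous sites (multiple indels or unusable trace?)"
            )

    notes: list[str] = []
    best_events = events(results[0])
    ties = {
        (r[2], r[3])
        for r in results
        if (r[0], events(r)) == (explained, best_events)
    }
    confidence = "high"
    if explained < 1.0:
        confidence = "low"
        notes.append("unexplained ambiguous positions remain")
    if len(ties) > 1:
        confidence = "low"
        notes.append("multiple equally parsimonious allele pairs")
    if amb_decode:
        confidence = "low"
        notes.append("allele decode not unique (ties or upstream heterozygous sites)")
    if indel is None and subs > 1:
        confidence = "low"
        notes.append("substitution-only heterozygote: linkage unknowable")
    return PhasedPair(a1, a2, indel, explained, confidence, subs, notes)


# ---------------------------------------------------------------------------
# catalog matching
# ---------------------------------------------------------------------------


@dataclass
class CatalogMatch:
    allele_1_id: str | None
    allele_2_id: str | None
    novel: list[str] = field(default_factory=list)
    homozygote_confirmed: bool = False


def match_against_catalog(
    pair: PhasedPair, catalog: dict[str, str]
) -> CatalogMatch:
    """Exact lookup of both phased alleles in a homozygote allele catalog.

    Novel alleles are flagged and listed, never silently merged.
    """
    for aid, seq in catalog.items():
        if set(seq.upper()) - _UNAMB:
            raise ValueError(f"catalog allele {aid!r} is not unambiguous")
    rev = {seq.upper(): aid for aid, seq in catalog.items()}
    id1 = rev.get(pair.allele_1)
    id2 = rev.get(pair.allele_2)
    novel = []
    if id1 is None:
        novel.append(pair.allele_1)
    if id2 is None and pair.allele_2 != pair.allele_1:
        novel.append(pair.allele_2)
    return CatalogMatch(
        id1, id2, novel,
        homozygote_confirmed=(id1 is not None and id1 == id2),
    )


def reconstruct_consensus(pair: PhasedPair) -> str:
    """IUPAC overlay of the phased alleles (identity check against input)."""
    return iupac_overlay(pair.allele_1, pair.allele_2)
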