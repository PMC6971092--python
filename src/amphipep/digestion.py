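"""Rule-based protease digestion and peptide-release feasibility.

Cleavage rules follow the classical specificity notation: the enzyme cuts on
one side of a recognition residue (P1 for C-terminal-side cutters like
trypsin, P1' for N-terminal-side cutters like Asp-N), cleavage is suppressed
entirely when the residue on the other side of the bond is in the blocked
set (trypsin: proline in P1'), and sites whose neighbour is in the slow set
(trypsin: acidic P1') hydrolyse slowly enough that both regimes - cutting
them and skipping them - are of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import PeptideCandidate, ProteinRecord, ValidationError


@dataclass(frozen=True)
class CleavageRule:
    name: str
    p1: frozenset[str]  # recognition residues
    blocked_p1_prime: frozenset[str] = frozenset()
    slow_p1_prime: frozenset[str] = frozenset()
    direction: str = "c"  # "c": cleave after P1; "n": cleave before P1'

    def __post_init__(self) -> None:
        if self.direction not in ("c", "n"):
            raise ValidationError("direction must be 'c' or 'n'")
        if self.blocked_p1_prime & self.slow_p1_prime:
            raise ValidationError("blocked and slow P1' sets must be disjoint")


TRYPSIN = CleavageRule(
    name="trypsin",
    p1=frozenset("KR"),
    blocked_p1_prime=frozenset("P"),
    slow_p1_prime=frozenset("DE"),
)

ASP_N = CleavageRule(name="asp-n", p1=frozenset("D"), direction="n")


@dataclass(frozen=True)
class Fragment:
    start: int  # 1-based inclusive on the parent
    end: int
    sequence: str
    skipped_slow_sites: tuple[int, ...] = ()  # P1 positions of skipped slow sites inside

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def cleavage_sites(sequence: str, rule: CleavageRule, skip_slow_sites: bool = False) -> list[int]:
    """Positions i (1-based) such that the bond between residues i and i+1 is cut."""
    sites = []
    for i in range(1, len(sequence)):  # bond after residue i
        if rule.direction == "c":
            recog, neighbour = sequence[i - 1], sequence[i]
        else:
            recog, neighbour = sequence[i], sequence[i - 1]
        if recog not in rule.p1:
            continue
        if neighbour in rule.blocked_p1_prime:
            continue
        if skip_slow_sites and neighbour in rule.slow_p1_prime:
            continue
        sites.append(i)
    return sites


def _slow_sites(sequence: str, rule: CleavageRule) -> set[int]:
    return set(cleavage_sites(sequence, rule, False)) - set(
        cleavage_sites(sequence, rule, True)
    )


def digest(sequence: str, rule: CleavageRule, skip_slow_sites: bool = False) -> list[Fragment]:
    """Fully digest the sequence; fragments tile the parent exactly."""
    sites = cleavage_sites(sequence, rule, skip_slow_sites)
    slow = _slow_sites(sequence, rule) if skip_slow_sites else set()
    fragments = []
    prev = 0
    for cut in sites + [len(sequence)]:
        skipped = tuple(s for s in sorted(slow) if prev < s < cut)
        fragments.append(
            Fragment(
                start=prev + 1,
                end=cut,
                sequence=sequence[prev:cut],
                skipped_slow_sites=skipped,
            )
        )
        prev = cut
    return fragments


def digest_with_missed_cleavages(
    sequence: str, rule: CleavageRule, max_missed: int = 2
) -> list[Fragment]:
    """Enumerate fragments with up to ``max_missed`` missed cleavages."""
    base = digest(sequence, rule, False)
    out: list[Fragment] = []
    for i in range(len(base)):
        for j in range(i, min(i + max_missed + 1, len(base))):
            out.append(
                Fragment(
                    start=base[i].start,
                    end=base[j].end,
                    sequence=sequence[base[i].start - 1 : base[j].end],
                )
            )
    return out


def theoretical_peptide_count(
    sequence: str, rule: CleavageRule = TRYPSIN, min_len: int = 6, max_len: int = 30
) -> int:
    """Count fully-cleaved fragments with min_len <= length <= max_len.

    This is the denominator used for intensity-based absolute quantification.
    """
    return sum(1 for f in digest(sequence, rule, False) if min_len <= f.length <= max_len)


@dataclass(frozen=True)
class RegimeOutcome:
    skip_slow_sites: bool
    fragment: Fragment  # fragment with maximal overlap with the target
    n_term_truncation: int  # target residues lost at the N side
    c_term_truncation: int
    n_term_elongation: int  # extra fragment residues beyond the target
    c_term_elongation: int


@dataclass(frozen=True)
class ReleaseReport:
    target: PeptideCandidate
    parent_id: str
    internal_fast_sites: int
    outcomes: tuple[RegimeOutcome, ...]
    verdict: str  # "feasible" | "feasible with truncation/elongation" | "infeasible as intact peptide"

    def best(self, skip_slow_sites: bool = True) -> RegimeOutcome:
        for o in self.outcomes:
            if o.skip_slow_sites == skip_slow_sites:
                return o
        raise KeyError(skip_slow_sites)


def _best_overlap(fragments: list[Fragment], start: int, end: int) -> Fragment:
    def overlap(f: Fragment) -> int:
        return max(0, min(f.end, end) - max(f.start, start) + 1)

    return max(fragments, key=lambda f: (overlap(f), -f.length))


def release_feasibility(
    target: PeptideCandidate, parent: ProteinRecord, rule: CleavageRule = TRYPSIN
) -> ReleaseReport:
    """Assess whether the digest can release the target from its parent.

    The parent is digested under both slow-site regimes; for each the fragment
    maximally overlapping the target is reported with truncation/elongation
    counts. Fast cleavage sites strictly inside the target make an intact
    release impossible.
    """
    seq = parent.sequence
    if seq[target.start - 1 : target.end] != target.sequence:
        raise ValidationError(
            f"target sequence does not match parent {parent.id!r} at "
            f"{target.start}-{target.end}"
        )
    fast = set(cleavage_sites(seq, rule, skip_slow_sites=True))
    internal_fast = sum(1 for s in fast if target.start <= s < target.end)

    outcomes = []
    exact = False
    for skip in (False, True):
        frags = digest(seq, rule, skip_slow_sites=skip)
        frag = _best_overlap(frags, target.start, target.end)
        outcome = RegimeOutcome(
            skip_slow_sites=skip,
            fragment=frag,
            n_term_truncation=max(0, frag.start - target.start),
            c_term_truncation=max(0, target.end - frag.end),
            n_term_elongation=max(0, target.start - frag.start),
            c_term_elongation=max(0, frag.end - target.end),
        )
        outcomes.append(outcome)
        if (frag.start, frag.end) == (target.start, target.end):
            exact = True

    if internal_fast > 0:
        verdict = "infeasible as intact peptide"
    elif exact:
        verdict = "feasible"
    else:
        verdict = "feasible with truncation/elongation"
    return ReleaseReport(
        target=target,
        parent_id=parent.id,
        internal_fast_sites=internal_fast,
        outcomes=tuple(outcomes),
        verdict=verdict,
    )


def format_release_report(report: ReleaseReport, parent: ProteinRecord, window: int = 15) -> str:
    """Human-readable block: target region with +/- ``window`` residues of
    context, recognition residues marked, and per-regime outcomes.
    """
    seq = parent.sequence
    t = report.target
    lo = max(1, t.start - window)
    hi = min(len(seq), t.end + window)
    marked = []
    for pos in range(lo, hi + 1):
        aa = seq[pos - 1]
        if aa in "KR":
            aa = f"[{aa}]"
        if pos == t.start:
            aa = "{" + aa
        if pos == t.end:
            aa = aa + "}"
        marked.append(aa)
    lines = [
        f"target {t.parent_id} {t.start}-{t.end} ({t.sequence})",
        "context " + "".join(marked),
        f"internal fast sites: {report.internal_fast_sites}",
    ]
    for o in report.outcomes:
        regime = "slow sites skipped" if o.skip_slow_sites else "full cleavage"
        lines.append(
            f"  [{regime}] fragment {o.fragment.start}-{o.fragment.end} "
            f"{o.fragment.sequence} trunc N{o.n_term_truncation}/C{o.c_term_truncation} "
            f"elong N{o.n_term_elongation}/C{o.c_term_elongation}"
        )
    lines.append(f"verdict: {report.verdict}")
    return "\n".join(lines)
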