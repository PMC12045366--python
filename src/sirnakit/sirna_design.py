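"""Scoring and ranking of candidate siRNA target sites.

Candidates are scored on the classic empirical design axes:

* G+C fraction of the target window;
* thermodynamic end asymmetry of the guide/passenger duplex, from
  nearest-neighbor stack free energies (dG37) — a guide whose 5' end is
  the less stable duplex end is preferentially loaded into RISC;
* self-complementarity, a gapless self-dimer propensity proxy;
* seed-region (guide positions 2-8 by default) match load against
  off-target mRNA / lncRNA collections, the driver of miRNA-like
  off-target repression.

A configurable rule set turns the metrics into pass/fail filters and a
composite z-score ranking of the passing candidates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .transcript_model import (
    Region,
    SetRole,
    TargetSite,
    Transcript,
    TranscriptSet,
    normalize_rna,
    reverse_complement,
)

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


# ---------------------------------------------------------------------------
# Nearest-neighbor parameters


@dataclass(frozen=True)
class NNParameterTable:
    """RNA nearest-neighbor dG37 stack table plus non-stack terms."""

    stacks: dict[str, float]
    init: float
    terminal_au: float

    def __post_init__(self) -> None:
        missing = {a + b for a in "ACGU" for b in "ACGU"} - set(self.stacks)
        if missing:
            raise ValueError(f"NN table missing stacks: {sorted(missing)}")
        values = list(self.stacks.values()) + [self.init, self.terminal_au]
        if not all(np.isfinite(values)):
            raise ValueError("NN table contains non-finite values")


def load_nn_table() -> NNParameterTable:
    """Load the packaged dG37 nearest-neighbor table."""
    path = importlib.resources.files("sirnakit.data") / "nn_dg37.tsv"
    table = pd.read_csv(path, sep="\t", comment="#")
    stacks = {}
    extras = {}
    for row in table.itertuples():
        if len(row.stack) == 2:
            stacks[row.stack] = float(row.dg37)
        else:
            extras[row.stack] = float(row.dg37)
    return NNParameterTable(
        stacks=stacks, init=extras["init"], terminal_au=extras["terminal_AU"]
    )


_DEFAULT_NN: Optional[NNParameterTable] = None


def _nn_table(table: Optional[NNParameterTable]) -> NNParameterTable:
    global _DEFAULT_NN
    if table is not None:
        return table
    if _DEFAULT_NN is None:
        _DEFAULT_NN = load_nn_table()
    return _DEFAULT_NN


# ---------------------------------------------------------------------------
# Elementary metrics


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length of an RNA string."""
    seq = normalize_rna(sequence)
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def duplex_end_dg(
    duplex_strand: str,
    end: str = "5prime",
    n_pairs: int = 4,
    nn_table: Optional[NNParameterTable] = None,
) -> float:
    """Stacked dG37 of the terminal ``n_pairs`` base pairs of a duplex.

    ``duplex_strand`` is one strand of a fully complementary duplex read
    5'->3'; the sum runs over the ``n_pairs - 1`` nearest-neighbor stacks
    at the chosen end.  No initiation term is included so that the two
    ends of a duplex are directly comparable.
    """
    seq = normalize_rna(duplex_strand)
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if n_pairs > len(seq):
        raise ValueError(
            f"n_pairs {n_pairs} exceeds duplex length {len(seq)}"
        )
    if end not in {"5prime", "3prime"}:
        raise ValueError("end must be '5prime' or '3prime'")
    window = seq[:n_pairs] if end == "5prime" else seq[-n_pairs:]
    table = _nn_table(nn_table)
    return sum(table.stacks[window[i:i + 2]] for i in range(n_pairs - 1))


def asymmetry_score(
    guide: str,
    n_pairs: int = 4,
    nn_table: Optional[NNParameterTable] = None,
) -> float:
    """Duplex end-stability asymmetry of a guide strand, in kcal/mol.

    ddG = dG(guide 5'-end pairs) - dG(guide 3'-end pairs).  Positive
    values mean the guide 5' end is the less stable duplex end (its
    stacks are less negative), which favors guide-strand loading.
    Swapping strand roles exactly negates the score.
    """
    return duplex_end_dg(guide, "5prime", n_pairs, nn_table) - duplex_end_dg(
        guide, "3prime", n_pairs, nn_table
    )


def self_comp_score(sequence: str) -> int:
    """Maximum Watson-Crick pair count of a gapless self-dimer.

    The sequence is aligned, at every offset, against its own reverse
    complement; the score is the best number of paired positions over
    all offsets.  A perfect palindrome of length L scores L.
    """
    seq = normalize_rna(sequence)
    n = len(seq)
    if n < 4:
        raise ValueError("sequence shorter than 4 nt")
    rc = reverse_complement(seq)
    best = 0
    for offset in range(-(n - 1), n):
        count = 0
        for i in range(n):
            j = i + offset
            if 0 <= j < n and seq[i] == rc[j]:
                count += 1
        best = max(best, count)
    return best


def seed_sequence(guide: str, seed_start: int = 2, seed_end: int = 8) -> str:
    """Guide seed region, 1-based inclusive positions (default 2-8)."""
    guide = normalize_rna(guide)
    if seed_end > len(guide):
        raise ValueError(
            f"guide length {len(guide)} shorter than seed_end {seed_end}"
        )
    if not 1 <= seed_start < seed_end:
        raise ValueError("require 1 <= seed_start < seed_end")
    return guide[seed_start - 1:seed_end]


def _count_overlapping(needle: str, haystack: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def seed_matches(
    guide: str,
    transcript_set: TranscriptSet,
    seed_start: int = 2,
    seed_end: int = 8,
    scan_region: str = "utr3",
) -> int:
    """Count seed-complement occurrences in an off-target collection.

    The reverse complement of the guide seed is scanned, with overlaps,
    against each transcript's 3'UTR when a CDS is annotated (the
    canonical miRNA-like off-target region), or the full sequence
    otherwise.  ``scan_region='full'`` forces full-transcript scans.
    """
    if scan_region not in {"utr3", "full"}:
        raise ValueError("scan_region must be 'utr3' or 'full'")
    target_motif = reverse_complement(seed_sequence(guide, seed_start, seed_end))
    total = 0
    for transcript in transcript_set:
        if scan_region == "utr3" and transcript.cds is not None:
            region = transcript.sequence[transcript.cds[1]:]
        else:
            region = transcript.sequence
        total += _count_overlapping(target_motif, region)
    return total


# ---------------------------------------------------------------------------
# Rules and ranking


@dataclass
class DesignRules:
    """Pass/fail thresholds and ranking configuration.

    ``max_seed_matches`` has no universal default and must be set
    explicitly when off-target sets are scanned; ``None`` disables the
    seed filter.
    """

    gc_min: float = 0.30
    gc_max: float = 0.55
    asymmetry_min: float = 0.0
    seed_start: int = 2
    seed_end: int = 8
    max_seed_matches: Optional[int] = None
    self_comp_max: int = 8
    top_n: int = 24
    end_pairs: int = 4
    scan_region: str = "utr3"
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "asymmetry": 1.0,
            "gc_centrality": 1.0,
            "self_comp": 1.0,
            "seed_matches": 1.0,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_min <= self.gc_max <= 1.0:
            raise ValueError("require 0 <= gc_min <= gc_max <= 1")
        if not 1 <= self.seed_start < self.seed_end:
            raise ValueError("require 1 <= seed_start < seed_end")


@dataclass
class CandidateScore:
    """All design criteria for one candidate site."""

    site: TargetSite
    guide_sequence: str
    gc: float
    dg_5prime_guide_end: float
    dg_3prime_guide_end: float
    asymmetry: float
    self_comp: int
    seed_matches_mRNA: int
    seed_matches_lncRNA: int
    passes: dict[str, bool]
    composite: float = float("nan")
    rank: Optional[int] = None

    @property
    def passed(self) -> bool:
        return all(self.passes.values())


def _zscores(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def score_site(
    site: TargetSite,
    rules: DesignRules,
    off_target_mrna: Optional[TranscriptSet] = None,
    off_target_lncrna: Optional[TranscriptSet] = None,
    nn_table: Optional[NNParameterTable] = None,
) -> CandidateScore:
    """Compute every design criterion for a single site."""
    guide = reverse_complement(site.site_sequence)
    gc = gc_fraction(site.site_sequence)
    dg5 = duplex_end_dg(guide, "5prime", rules.end_pairs, nn_table)
    dg3 = duplex_end_dg(guide, "3prime", rules.end_pairs, nn_table)
    asym = dg5 - dg3
    sc = self_comp_score(site.site_sequence)
    sm_m = (
        seed_matches(guide, off_target_mrna, rules.seed_start,
                     rules.seed_end, rules.scan_region)
        if off_target_mrna is not None else 0
    )
    sm_l = (
        seed_matches(guide, off_target_lncrna, rules.seed_start,
                     rules.seed_end, rules.scan_region)
        if off_target_lncrna is not None else 0
    )
    passes = {
        "gc": rules.gc_min <= gc <= rules.gc_max,
        "asymmetry": asym >= rules.asymmetry_min,
        "self_comp": sc <= rules.self_comp_max,
        "seed_matches": (
            rules.max_seed_matches is None
            or (sm_m + sm_l) <= rules.max_seed_matches
        ),
    }
    return CandidateScore(
        site=site,
        guide_sequence=guide,
        gc=gc,
        dg_5prime_guide_end=dg5,
        dg_3prime_guide_end=dg3,
        asymmetry=asym,
        self_comp=sc,
        seed_matches_mRNA=sm_m,
        seed_matches_lncRNA=sm_l,
        passes=passes,
    )


def rank_candidates(
    sites: Sequence[TargetSite],
    rules: DesignRules,
    off_target_mrna: Optional[TranscriptSet] = None,
    off_target_lncrna: Optional[TranscriptSet] = None,
    nn_table: Optional[NNParameterTable] = None,
) -> list[CandidateScore]:
    """Score all sites, filter by rules, and rank the passing candidates.

    The composite score is a weighted sum of z-scored criteria computed
    over all candidates: asymmetry (+), GC centrality within the allowed
    window (+), self-complementarity (-), total seed matches (-).
    Passing candidates get ranks 1..n by descending composite with ties
    broken by fewer seed matches, higher asymmetry, then lower start.
    The returned list contains every candidate (passers first, in rank
    order; non-passers after, by start) and is invariant to the input
    ordering of sites.
    """
    if not sites:
        raise ValueError("no sites to rank")
    scored = [
        score_site(s, rules, off_target_mrna, off_target_lncrna, nn_table)
        for s in sites
    ]
    gc_mid = 0.5 * (rules.gc_min + rules.gc_max)
    asym = _zscores(np.array([c.asymmetry for c in scored]))
    gc_cent = _zscores(np.array([-abs(c.gc - gc_mid) for c in scored]))
    selfc = _zscores(np.array([float(c.self_comp) for c in scored]))
    seeds = _zscores(
        np.array([float(c.seed_matches_mRNA + c.seed_matches_lncRNA)
                  for c in scored])
    )
    w = rules.weights
    for c, a, g, s, m in zip(scored, asym, gc_cent, selfc, seeds):
        c.composite = (
            w["asymmetry"] * a + w["gc_centrality"] * g
            - w["self_comp"] * s - w["seed_matches"] * m
        )

    def sort_key(c: CandidateScore):
        return (
            -c.composite,
            c.seed_matches_mRNA + c.seed_matches_lncRNA,
            -c.asymmetry,
            c.site.start,
        )

    passers = sorted((c for c in scored if c.passed), key=sort_key)
    for i, c in enumerate(passers, start=1):
        c.rank = i
    failers = sorted((c for c in scored if not c.passed),
                     key=lambda c: c.site.start)
    return passers + failers


def top_candidates(
    candidates: Sequence[CandidateScore], top_n: int
) -> list[CandidateScore]:
    """View of the top-``top_n`` ranked passing candidates."""
    return [c for c in candidates if c.rank is not None][:top_n]


def candidates_to_frame(candidates: Sequence[CandidateScore]) -> pd.DataFrame:
    """One row per candidate with all criteria, pass flags, and rank."""
    rows = []
    for c in candidates:
        rows.append({
            "transcript_id": c.site.transcript_id,
            "start": c.site.start,
            "end": c.site.end,
            "region": c.site.region.value,
            "site_sequence": c.site.site_sequence,
            "guide_sequence": c.guide_sequence,
            "gc": c.gc,
            "dg_5prime_guide_end": c.dg_5prime_guide_end,
            "dg_3prime_guide_end": c.dg_3prime_guide_end,
            "asymmetry": c.asymmetry,
            "self_comp": c.self_comp,
            "seed_matches_mRNA": c.seed_matches_mRNA,
            "seed_matches_lncRNA": c.seed_matches_lncRNA,
            "passed": c.passed,
            "composite": c.composite,
            "rank": c.rank,
        })
    return pd.DataFrame(rows)
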