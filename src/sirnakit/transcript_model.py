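"""Multi-isoform transcript models and candidate target-site enumeration.

A :class:`Transcript` is an RNA sequence with transcript-relative exon
boundaries and an optional CDS, all in 0-based half-open coordinates.
Candidate silencing sites are fixed-length windows enumerated over the
full transcript (5'UTR, ORF and 3'UTR alike); isoform-exclusive windows
and cross-species conservation are decided by exact substring matching.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_RNA_ALPHABET = set("ACGU")

DEFAULT_SITE_LENGTH = 20


def normalize_rna(sequence: str) -> str:
    """Uppercase a sequence and convert DNA T to RNA U.

    Raises ``ValueError`` on characters outside {A, C, G, U, T}.
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU/T characters in sequence: {sorted(bad)}")
    return seq


_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an RNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]


class Region(str, Enum):
    """Transcript region a target site falls in."""

    UTR5 = "UTR5"
    ORF = "ORF"
    UTR3 = "UTR3"
    JUNCTION = "junction-spanning"


class SetRole(str, Enum):
    TARGET = "target"
    OFF_TARGET_MRNA = "off_target_mRNA"
    OFF_TARGET_LNCRNA = "off_target_lncRNA"
    ORTHOLOG = "ortholog"


@dataclass
class Transcript:
    """One transcript isoform.

    Parameters
    ----------
    id : str
        Unique transcript identifier.
    sequence : str
        RNA sequence over {A, C, G, U}; DNA input is normalized on
        construction.
    species : str
        Species tag, free text.
    isoform_label : str
        Isoform name within the gene, e.g. ``"E1"`` or ``"E2"``.
    exon_boundaries : list of (start, end)
        Transcript-relative exon intervals, 0-based half-open, that must
        tile ``[0, len(sequence))`` contiguously.
    cds : (start, end), optional
        Coding region in transcript coordinates, 0-based half-open.
    """

    id: str
    sequence: str
    species: str = ""
    isoform_label: str = ""
    exon_boundaries: list[tuple[int, int]] = field(default_factory=list)
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if not self.exon_boundaries:
            self.exon_boundaries = [(0, len(self.sequence))]
        self._validate()

    def _validate(self) -> None:
        bounds = self.exon_boundaries
        expected_start = 0
        for start, end in bounds:
            if start != expected_start or end <= start:
                raise ValueError(
                    f"transcript {self.id!r}: exon boundaries {bounds} do not "
                    f"tile [0, {len(self.sequence)}) contiguously"
                )
            expected_start = end
        if expected_start != len(self.sequence):
            raise ValueError(
                f"transcript {self.id!r}: exons end at {expected_start}, "
                f"sequence length is {len(self.sequence)}"
            )
        if self.cds is not None:
            cs, ce = self.cds
            if not (0 <= cs < ce <= len(self.sequence)):
                raise ValueError(
                    f"transcript {self.id!r}: cds {self.cds} outside "
                    f"[0, {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptSet:
    """A collection of transcripts with a role in the design workflow."""

    transcripts: list[Transcript]
    role: SetRole = SetRole.TARGET

    def __post_init__(self) -> None:
        if isinstance(self.role, str):
            self.role = SetRole(self.role)
        ids = [t.id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transcript ids: {dupes}")

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def get(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass
class TargetSite:
    """A candidate siRNA target window on a transcript."""

    transcript_id: str
    start: int
    length: int
    site_sequence: str
    region: Region
    overlapped_exons: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 8:
            raise ValueError("site length must be >= 8")
        if len(self.site_sequence) != self.length:
            raise ValueError("site_sequence length disagrees with length field")

    @property
    def end(self) -> int:
        return self.start + self.length


# ---------------------------------------------------------------------------
# Loading


def _read_structure_table(path: Path) -> pd.DataFrame:
    """Read exon/CDS structure from a 4-column TSV or a GFF3-style file.

    TSV columns: transcript_id, start, end, feature (feature in
    {exon, CDS}).  GFF3: seqid is interpreted as the transcript id and
    columns 4/5 as 1-based inclusive coordinates of exon/CDS features.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff"):
        gff = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
        )
        gff = gff[gff["type"].isin(["exon", "CDS"])]
        return pd.DataFrame({
            "transcript_id": gff["seqid"],
            "start": gff["start"].astype(int) - 1,  # GFF is 1-based inclusive
            "end": gff["end"].astype(int),
            "feature": gff["type"],
        })
    table = pd.read_csv(
        path, sep="\t", header=None,
        names=["transcript_id", "start", "end", "feature"], comment="#",
    )
    if table.iloc[0]["transcript_id"] == "transcript_id":  # optional header row
        table = table.iloc[1:].reset_index(drop=True)
    table["start"] = table["start"].astype(int)
    table["end"] = table["end"].astype(int)
    return table


def load_transcripts(
    fasta_path: str | Path,
    structure_path: str | Path | None = None,
    role: SetRole | str = SetRole.TARGET,
    species: str = "",
) -> TranscriptSet:
    """Load a transcript set from FASTA plus optional structure annotation.

    Transcripts without structure records get a single exon spanning the
    whole sequence and no CDS.  DNA input (T) is stored as RNA (U).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    structure = None
    if structure_path is not None:
        structure = _read_structure_table(Path(structure_path))
        unknown = set(structure["transcript_id"]) - {r.id for r in records}
        if unknown:
            raise ValueError(
                f"structure refers to ids absent from FASTA: {sorted(unknown)}"
            )

    transcripts = []
    for rec in records:
        exons: list[tuple[int, int]] = []
        cds = None
        if structure is not None:
            rows = structure[structure["transcript_id"] == rec.id]
            exon_rows = rows[rows["feature"] == "exon"].sort_values("start")
            exons = [(int(r.start), int(r.end)) for r in exon_rows.itertuples()]
            cds_rows = rows[rows["feature"] == "CDS"]
            if len(cds_rows) > 0:
                cds = (int(cds_rows["start"].min()), int(cds_rows["end"].max()))
        transcripts.append(
            Transcript(
                id=rec.id,
                sequence=str(rec.seq),
                species=species,
                exon_boundaries=exons,
                cds=cds,
            )
        )
    return TranscriptSet(transcripts=transcripts, role=role)


# ---------------------------------------------------------------------------
# Site enumeration


def _label_region(transcript: Transcript, start: int, length: int) -> Region:
    """Region label by majority overlap; ties go to the more 5' region."""
    if transcript.cds is None:
        return Region.ORF
    cs, ce = transcript.cds
    end = start + length
    if end <= cs:
        return Region.UTR5
    if start >= ce:
        return Region.UTR3
    if start >= cs and end <= ce:
        return Region.ORF
    # straddles one or both boundaries: majority overlap, tie -> 5'-most
    overlaps = [
        (Region.UTR5, max(0, min(end, cs) - start)),
        (Region.ORF, max(0, min(end, ce) - max(start, cs))),
        (Region.UTR3, max(0, end - max(start, ce))),
    ]
    best = max(o for _, o in overlaps)
    for region, o in overlaps:  # 5'-to-3' order resolves ties toward 5'
        if o == best:
            return region
    raise AssertionError("unreachable")


def _overlapped_exons(transcript: Transcript, start: int, end: int) -> list[int]:
    return [
        i for i, (es, ee) in enumerate(transcript.exon_boundaries)
        if es < end and start < ee
    ]


def enumerate_sites(
    transcript: Transcript, length: int = DEFAULT_SITE_LENGTH
) -> list[TargetSite]:
    """Enumerate every length-``length`` window of a transcript as a site.

    Returns ``len(sequence) - length + 1`` sites in ascending start order.
    Sites on a transcript without CDS annotation are labeled ORF.
    """
    L = len(transcript.sequence)
    if length > L:
        raise ValueError(f"site length {length} exceeds transcript length {L}")
    sites = []
    for start in range(L - length + 1):
        end = start + length
        region = (
            Region.ORF if transcript.cds is None
            else _label_region(transcript, start, length)
        )
        sites.append(
            TargetSite(
                transcript_id=transcript.id,
                start=start,
                length=length,
                site_sequence=transcript.sequence[start:end],
                region=region,
                overlapped_exons=_overlapped_exons(transcript, start, end),
            )
        )
    return sites


def isoform_exclusive_sites(
    sites: Sequence[TargetSite], other_isoform: Transcript
) -> list[TargetSite]:
    """Sites whose sequence never occurs in the other isoform.

    Exact same-strand substring matching; junction-spanning sites are
    eligible like any other.
    """
    other = other_isoform.sequence
    return [s for s in sites if s.site_sequence not in other]


def site_conservation(
    site: TargetSite, ortholog_sets: Sequence[TranscriptSet]
) -> tuple[dict[str, bool], bool]:
    """Per-species exact conservation of a site, plus an overall flag.

    A species conserves the site iff the site sequence occurs exactly
    (0 mismatches, same strand) in at least one ortholog transcript of
    that species.  The overall flag is the conjunction over species; an
    empty species list yields a vacuous ``True`` with a warning.
    """
    if not ortholog_sets:
        warnings.warn("site_conservation called with no ortholog sets; "
                      "overall flag is vacuously true")
        return {}, True
    per_species: dict[str, bool] = {}
    for tset in ortholog_sets:
        if tset.role != SetRole.ORTHOLOG:
            raise ValueError(f"expected ortholog set, got role {tset.role}")
        species = tset.transcripts[0].species if tset.transcripts else ""
        per_species[species] = any(
            site.site_sequence in t.sequence for t in tset.transcripts
        )
    return per_species, all(per_species.values())


# ---------------------------------------------------------------------------
# Export


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """BED-like table of sites (transcript_id, start, end, region, sequence)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "region": s.region.value,
                "sequence": s.site_sequence,
            }
            for s in sites
        ]
    )
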