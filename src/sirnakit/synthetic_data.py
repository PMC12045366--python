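"""Ground-truth-bearing generators for every pipeline input.

Each generator is deterministic given its seed and returns (or writes)
both the synthetic input and the ground truth needed to verify the
corresponding analysis stage: a two-isoform gene with known
isoform-exclusive windows, ortholog sets with known per-site
conservation, screen plates with known true knockdown fractions, 4PL
dose-response tables with known parameters, and two-channel microscopy
slides with known per-region positive fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imaging_quant import TwoChannelImage
from .transcript_model import (
    SetRole,
    Transcript,
    TranscriptSet,
    DEFAULT_SITE_LENGTH,
)

_BASES = np.array(list("ACGU"))

# Default screen/dose-response conditions used throughout: a single
# 1.5 uM screen concentration and 7 two-fold dilutions from 1.5 uM,
# 3 replicates, 10% multiplicative noise.
SCREEN_CONCENTRATION_M = 1.5e-6
DEFAULT_DOSES_M = tuple(SCREEN_CONCENTRATION_M / 2 ** i for i in range(7))
DEFAULT_REPLICATES = 3
DEFAULT_NOISE_CV = 0.10


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _lognormal_factor(
    rng: np.random.Generator, cv: float, size=None
) -> np.ndarray | float:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Gene / ortholog generators


def make_isoform_gene(
    seed: int = 0,
    exclusive_exon_len: int = 120,
    alt_first_exon_len: int = 90,
    shared_exon_lens: Sequence[int] = (150, 300),
    site_length: int = DEFAULT_SITE_LENGTH,
    utr5_len: int = 30,
    utr3_len: int = 100,
) -> tuple[TranscriptSet, dict]:
    """Generate a two-isoform gene with a known exclusive first exon.

    Isoform E1 carries an exclusive first exon; isoform E2 starts with
    an alternative first exon and shares all downstream exons with E1.
    Ground truth lists every E1 site start whose ``site_length``-mer is
    absent from E2, established by brute-force substring scan.
    """
    rng = np.random.default_rng(seed)
    exclusive = _random_rna(rng, exclusive_exon_len)
    alt_first = _random_rna(rng, alt_first_exon_len)
    shared = [_random_rna(rng, n) for n in shared_exon_lens]

    def build(tid: str, label: str, first: str) -> Transcript:
        parts = ([first] if first else []) + shared
        seq = "".join(parts)
        bounds = []
        pos = 0
        for p in parts:
            bounds.append((pos, pos + len(p)))
            pos += len(p)
        cds = None
        if len(seq) > utr5_len + utr3_len + 3:
            cds = (utr5_len, len(seq) - utr3_len)
        return Transcript(
            id=tid, sequence=seq, species="synthetic",
            isoform_label=label, exon_boundaries=bounds, cds=cds,
        )

    e1 = build("GENE-E1", "E1", exclusive)
    e2 = build("GENE-E2", "E2", alt_first)
    # brute-force ground truth: E1 k-mers absent from E2
    exclusive_starts = [
        start
        for start in range(len(e1.sequence) - site_length + 1)
        if e1.sequence[start:start + site_length] not in e2.sequence
    ]
    truth = {
        "site_length": site_length,
        "exclusive_exon_len": exclusive_exon_len,
        "exclusive_site_starts": exclusive_starts,
    }
    return TranscriptSet([e1, e2], role=SetRole.TARGET), truth


def make_orthologs(
    transcript: Transcript,
    species_divergence: dict[str, float],
    protect_intervals: Sequence[tuple[int, int]] = (),
    site_length: int = DEFAULT_SITE_LENGTH,
    seed: int = 0,
) -> tuple[list[TranscriptSet], pd.DataFrame]:
    """Diverged ortholog copies of a transcript, one set per species.

    Substitution-only divergence at the per-species rate; positions in
    ``protect_intervals`` (0-based half-open) never mutate.  Ground
    truth reports, per species and site start, whether the site window
    is substitution-free (hence exactly conserved).
    """
    rng = np.random.default_rng(seed)
    base = np.array(list(transcript.sequence))
    L = len(base)
    protected = np.zeros(L, dtype=bool)
    for start, end in protect_intervals:
        if not 0 <= start < end <= L:
            raise ValueError(f"protect interval {(start, end)} out of range")
        protected[start:end] = True

    sets: list[TranscriptSet] = []
    truth_rows = []
    n_sites = L - site_length + 1
    for species, divergence in species_divergence.items():
        if not 0.0 <= divergence <= 1.0:
            raise ValueError(f"divergence for {species!r} not in [0, 1]")
        mutate = (rng.random(L) < divergence) & ~protected
        seq = base.copy()
        for i in np.flatnonzero(mutate):
            choices = [b for b in "ACGU" if b != base[i]]
            seq[i] = rng.choice(choices)
        ortholog = Transcript(
            id=f"{transcript.id}|{species}",
            sequence="".join(seq),
            species=species,
            isoform_label=transcript.isoform_label,
        )
        sets.append(TranscriptSet([ortholog], role=SetRole.ORTHOLOG))
        mutated_cum = np.concatenate([[0], np.cumsum(mutate.astype(int))])
        for start in range(n_sites):
            window_mut = mutated_cum[start + site_length] - mutated_cum[start]
            truth_rows.append({
                "species": species,
                "start": start,
                "conserved": window_mut == 0,
            })
    truth = pd.DataFrame(truth_rows)
    return sets, truth


# ---------------------------------------------------------------------------
# Screen / dose-response simulators


def simulate_screen(
    truth: dict[str, dict[str, float]],
    noise_cv: float = DEFAULT_NOISE_CV,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    hk_mean: float = 10_000.0,
    concentration: float = SCREEN_CONCENTRATION_M,
    n_controls: int = 3,
) -> pd.DataFrame:
    """Plate table for a single-dose screen with known true fractions.

    ``truth`` maps compound -> probe -> true remaining fraction.  Each
    well draws a housekeeping signal (lognormal around ``hk_mean``) and
    a target signal equal to housekeeping x truth x unit-mean lognormal
    noise.  NTC wells carry truth 1.0 for every probe present.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for compound, probes in truth.items():
        for probe, frac in probes.items():
            if frac < 0:
                raise ValueError(
                    f"negative truth fraction for {compound}/{probe}"
                )
    rng = np.random.default_rng(seed)
    probes = sorted({p for d in truth.values() for p in d})
    rows = []

    def add_wells(group: str, probe: str, frac: float, n: int, conc):
        for rep in range(n):
            hk = hk_mean * _lognormal_factor(rng, noise_cv)
            target = hk * frac * _lognormal_factor(rng, noise_cv)
            rows.append({
                "sample_id": f"{group}:{probe}:rep{rep + 1}",
                "group": group,
                "probe": probe,
                "target_signal": target,
                "housekeeping_signal": hk,
                "concentration": conc,
            })

    for probe in probes:
        add_wells("NTC", probe, 1.0, n_controls, None)
    for compound in sorted(truth):
        for probe, frac in sorted(truth[compound].items()):
            add_wells(f"treated:{compound}", probe, frac, replicates,
                      concentration)
    return pd.DataFrame(rows)


def simulate_dose_response(
    bottom: float = 0.1,
    top: float = 1.0,
    hill: float = 1.0,
    ic50: float = 201e-9,
    doses: Sequence[float] = DEFAULT_DOSES_M,
    replicates: int = DEFAULT_REPLICATES,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative-expression table drawn from a 4PL with known parameters."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in doses:
        expected = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
        for rep in range(replicates):
            rows.append({
                "concentration": conc,
                "replicate": rep + 1,
                "response": expected * _lognormal_factor(rng, noise_cv),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Slide renderer


@dataclass
class SlideParams:
    """Synthetic two-channel slide layout and noise model.

    Regions are equal-width vertical strips, one per entry of
    ``positive_fractions``, each holding ``n_nuclei_per_region``
    non-overlapping disk nuclei.  Marker signal amplitude over
    background is ``snr`` times the additive noise standard deviation.
    """

    shape: tuple[int, int] = (1024, 1024)
    n_nuclei_per_region: int = 750
    positive_fractions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.1, "B": 0.5}
    )
    radius_range: tuple[int, int] = (4, 7)
    min_gap: int = 2
    snr: float = 10.0
    noise_sd: float = 2.0
    dapi_background: float = 5.0
    dapi_nucleus: float = 60.0
    marker_background: float = 20.0
    background_kind: str = "constant"  # or "ramp"
    max_placement_tries: int = 200


def _region_masks(shape: tuple[int, int], names: Sequence[str]) -> dict[str, np.ndarray]:
    masks = {}
    width = shape[1] // len(names)
    for i, name in enumerate(names):
        mask = np.zeros(shape, dtype=bool)
        stop = shape[1] if i == len(names) - 1 else (i + 1) * width
        mask[:, i * width:stop] = True
        masks[name] = mask
    return masks


def render_slide(
    params: SlideParams | None = None, seed: int = 0
) -> tuple[TwoChannelImage, pd.DataFrame]:
    """Render a two-channel slide with planted positive nuclei.

    Returns the image (with region masks attached) and a ground-truth
    table (region, row, col, radius, positive).  The planted positive
    count per region is ``round(n_nuclei * fraction)``.  Raises when
    non-overlapping placement fails repeatedly, suggesting a larger
    canvas.
    """
    p = params or SlideParams()
    rng = np.random.default_rng(seed)
    shape = p.shape
    names = list(p.positive_fractions)
    masks = _region_masks(shape, names)

    dapi = np.maximum(
        0.0, p.dapi_background + rng.normal(0.0, p.noise_sd, shape)
    )
    if p.background_kind == "constant":
        marker_bg = np.full(shape, p.marker_background)
    elif p.background_kind == "ramp":
        ramp = np.linspace(0.5, 1.5, shape[1])[None, :]
        marker_bg = p.marker_background * np.broadcast_to(ramp, shape).copy()
    else:
        raise ValueError(f"unknown background_kind {p.background_kind!r}")
    marker = np.maximum(0.0, marker_bg + rng.normal(0.0, p.noise_sd, shape))
    amplitude = p.snr * p.noise_sd

    placed_r: list[float] = []
    placed_c: list[float] = []
    placed_rad: list[float] = []
    truth_rows = []
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]

    for name in names:
        n = p.n_nuclei_per_region
        if n == 0:
            continue
        n_positive = round(n * p.positive_fractions[name])
        positive_flags = np.zeros(n, dtype=bool)
        positive_flags[:n_positive] = True
        rng.shuffle(positive_flags)
        cols_in_region = np.flatnonzero(masks[name][0])
        c_lo, c_hi = cols_in_region.min(), cols_in_region.max()
        for k in range(n):
            radius = int(rng.integers(p.radius_range[0], p.radius_range[1] + 1))
            for attempt in range(p.max_placement_tries):
                r = rng.uniform(radius + 1, shape[0] - radius - 1)
                c = rng.uniform(
                    max(radius + 1, c_lo), min(shape[1] - radius - 1, c_hi)
                )
                if placed_r:
                    d2 = (np.array(placed_r) - r) ** 2 + (np.array(placed_c) - c) ** 2
                    limit = np.array(placed_rad) + radius + p.min_gap
                    if np.any(d2 < limit ** 2):
                        continue
                break
            else:
                raise RuntimeError(
                    "could not place all nuclei without overlap; "
                    "use a larger canvas or fewer nuclei"
                )
            placed_r.append(r)
            placed_c.append(c)
            placed_rad.append(radius)
            rr = int(round(r))
            cc = int(round(c))
            lo_r, hi_r = rr - radius, rr + radius + 1
            lo_c, hi_c = cc - radius, cc + radius + 1
            disk = (
                (yy[lo_r:hi_r, lo_c:hi_c] - r) ** 2
                + (xx[lo_r:hi_r, lo_c:hi_c] - c) ** 2
            ) <= radius ** 2
            dapi[lo_r:hi_r, lo_c:hi_c][disk] = p.dapi_nucleus + rng.normal(
                0.0, p.noise_sd, int(disk.sum())
            )
            if positive_flags[k]:
                marker[lo_r:hi_r, lo_c:hi_c][disk] += amplitude
            truth_rows.append({
                "region": name,
                "row": r,
                "col": c,
                "radius": radius,
                "positive": bool(positive_flags[k]),
            })

    image = TwoChannelImage(
        dapi=np.maximum(dapi, 0.0),
        marker=np.maximum(marker, 0.0),
        region_masks=masks,
    )
    return image, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# File output helpers (round-trip with the pipeline readers)


def write_fasta(transcripts: TranscriptSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i:i + 70] + "\n")


def write_structure_tsv(transcripts: TranscriptSet, path: str | Path) -> None:
    """4-column structure TSV (transcript_id, start, end, feature)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for start, end in t.exon_boundaries:
                fh.write(f"{t.id}\t{start}\t{end}\texon\n")
            if t.cds is not None:
                fh.write(f"{t.id}\t{t.cds[0]}\t{t.cds[1]}\tCDS\n")


def write_slide(
    image: TwoChannelImage, truth: pd.DataFrame, prefix: str | Path
) -> dict[str, Path]:
    """Write a slide as TIFFs (channels + labeled region mask) and truth CSV."""
    import tifffile

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([image.dapi, image.marker]).astype(np.float32)
    image_path = prefix.with_suffix(".tif")
    tifffile.imwrite(image_path, stack)
    paths = {"image": image_path}
    if image.region_masks:
        labeled = np.zeros(image.dapi.shape, dtype=np.uint8)
        names = sorted(image.region_masks)
        for i, name in enumerate(names, start=1):
            labeled[image.region_masks[name]] = i
        mask_path = prefix.parent / (prefix.name + "_masks.tif")
        tifffile.imwrite(mask_path, labeled)
        names_path = prefix.parent / (prefix.name + "_masks.json")
        import json

        names_path.write_text(json.dumps({str(i): n for i, n in
                                          enumerate(names, start=1)}))
        paths["masks"] = mask_path
        paths["mask_names"] = names_path
    truth_path = prefix.parent / (prefix.name + "_truth.csv")
    truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    return paths
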