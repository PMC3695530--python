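"""Positive-probe calling and transfrag assembly from dual-fraction tiling arrays.

A probe is 'positive' only if, in every biological replicate separately, its
non-polyadenylated (NPA) intensity exceeds both the replicate's noise
threshold and the paired polyadenylated (PA) intensity: the PA channel is
used as a contamination reference so that PA carry-over into the NPA
fraction is not called as NPA transcription. Positive probes are chained
into transfrags under maxgap/minrun rules and a minimum-probe filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomeLayout, GenomicInterval, IntervalSet


@dataclass
class ProbeTrack:
    """Tiled probe positions with NPA and PA intensity matrices.

    ``npa``/``pa`` map chromosome -> (n_probes, n_replicates) arrays aligned
    with ``positions[chrom]`` (probe starts on the tiling grid).
    """

    layout: GenomeLayout
    positions: dict[str, np.ndarray]
    npa: dict[str, np.ndarray]
    pa: dict[str, np.ndarray]
    cell_type: str = ""

    def __post_init__(self) -> None:
        reps = {m[c].shape[1] for m in (self.npa, self.pa) for c in m}
        if len(reps) > 1:
            raise ValueError(f"replicate count mismatch across fractions: {reps}")
        for chrom, p in self.positions.items():
            if self.npa[chrom].shape[0] != len(p) or self.pa[chrom].shape[0] != len(p):
                raise ValueError(f"{chrom}: probe/intensity length mismatch")

    @property
    def n_replicates(self) -> int:
        return next(iter(self.npa.values())).shape[1]

    def all_npa(self) -> np.ndarray:
        """NPA intensities concatenated over chromosomes, (total_probes, reps)."""
        return np.vstack([self.npa[c] for c in self.positions])


@dataclass
class CallerConfig:
    """Probe-calling and assembly parameters.

    noise_quantile: per-replicate quantile of that replicate's NPA
    intensities defining the noise threshold (the platform's absolute noise
    level is not meaningful after normalization, so the threshold is
    scale-free). minrun/maxgap are the chaining parameters; transfrags with
    fewer than ``min_probes`` positive probes are discarded.
    """

    noise_quantile: float = 0.90
    minrun: int = 50
    maxgap: int = 40
    min_probes: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.noise_quantile < 1:
            raise ValueError("noise_quantile must be in (0,1)")
        if self.minrun <= 0 or self.maxgap < 0 or self.min_probes < 1:
            raise ValueError("invalid caller parameters")


@dataclass(frozen=True)
class Transfrag:
    """A contiguous transcribed fragment assembled from positive probes."""

    interval: GenomicInterval
    probe_count: int
    cell_type: str = ""
    probe_starts: tuple[int, ...] = field(default=())

    @property
    def span(self) -> int:
        return len(self.interval)


def noise_thresholds(track: ProbeTrack, config: CallerConfig) -> np.ndarray:
    """Per-replicate noise threshold: quantile of that replicate's NPA values."""
    return np.quantile(track.all_npa(), config.noise_quantile, axis=0)


def call_positive_probes(
    track: ProbeTrack, config: CallerConfig, thresholds=None
) -> dict[str, np.ndarray]:
    """Boolean positive mask per chromosome.

    Positive iff in EVERY replicate: NPA > noise threshold AND NPA > PA.
    Thresholds default to the per-replicate noise quantile but can be given
    explicitly (one per replicate).
    """
    thr = (
        np.asarray(thresholds, dtype=float)
        if thresholds is not None
        else noise_thresholds(track, config)
    )
    if thr.shape != (track.n_replicates,):
        raise ValueError("need one threshold per replicate")
    masks = {}
    for chrom in track.positions:
        npa, pa = track.npa[chrom], track.pa[chrom]
        ok = (npa > thr[None, :]) & (npa > pa)
        masks[chrom] = ok.all(axis=1)
    return masks


def assemble_transfrags(
    positive_positions: dict[str, np.ndarray],
    layout: GenomeLayout,
    config: CallerConfig,
    cell_type: str = "",
) -> list[Transfrag]:
    """Chain positive probes into transfrags.

    A chain breaks where the gap between one probe's end and the next
    probe's start exceeds maxgap. Chains whose genomic span (first start to
    last end) is below minrun, or with fewer than min_probes probes, are
    discarded. Output is disjoint and sorted.
    """
    plen = layout.probe_length
    out = []
    for chrom in layout.chromosomes:
        starts = positive_positions.get(chrom)
        if starts is None or len(starts) == 0:
            continue
        starts = np.sort(np.asarray(starts, dtype=np.int64))
        gaps = starts[1:] - (starts[:-1] + plen)
        breaks = np.flatnonzero(gaps > config.maxgap)
        chunks = np.split(starts, breaks + 1)
        for chunk in chunks:
            span = int(chunk[-1] + plen - chunk[0])
            if span < config.minrun or len(chunk) < config.min_probes:
                continue
            out.append(
                Transfrag(
                    interval=GenomicInterval(chrom, int(chunk[0]), int(chunk[-1] + plen)),
                    probe_count=len(chunk),
                    cell_type=cell_type,
                    probe_starts=tuple(int(s) for s in chunk),
                )
            )
    return out


def call_transfrags(
    track: ProbeTrack,
    config: CallerConfig,
    repeat_mask: IntervalSet | None = None,
) -> list[Transfrag]:
    """Full caller: positive probes -> assembly -> repeat masking."""
    masks = call_positive_probes(track, config)
    pos = {c: track.positions[c][masks[c]] for c in track.positions}
    tfs = assemble_transfrags(pos, track.layout, config, cell_type=track.cell_type)
    if repeat_mask is not None:
        tfs = mask_repeats(tfs, repeat_mask)
    return tfs


def mask_repeats(
    transfrags: list[Transfrag], repeat_mask: IntervalSet
) -> list[Transfrag]:
    """Drop any transfrag overlapping the repeat mask by >= 1 bp."""
    return [t for t in transfrags if not repeat_mask.overlaps(t.interval)]


def compare_transfrag_sets(
    set_a: list[Transfrag], set_b: list[Transfrag]
) -> dict[str, list[Transfrag]]:
    """Partition each set into shared (>=1 bp overlap with the other) and unique.

    Mirrors a two-set Venn comparison of transfrag catalogues between cell
    types; |shared| + |unique| = |set| exactly on each side.
    """
    iset_a = IntervalSet.from_intervals(t.interval for t in set_a)
    iset_b = IntervalSet.from_intervals(t.interval for t in set_b)
    out = {"shared_a": [], "unique_a": [], "shared_b": [], "unique_b": []}
    for t in set_a:
        out["shared_a" if iset_b.overlaps(t.interval) else "unique_a"].append(t)
    for t in set_b:
        out["shared_b" if iset_a.overlaps(t.interval) else "unique_b"].append(t)
    return out
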