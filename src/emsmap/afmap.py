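"""Pooled allele-frequency profiles and candidate-region localization.

The mapping signal: at interspecific marker sites the non-reference allele is
the wild-parent allele, so windows around a recessive causal lesion show a
mutant-pool frequency collapsing to ~0 (every mutant is homozygous for the
cultivated haplotype there) while the phenotypically wild-type pool drifts
toward 2/3 (2 heterozygous : 1 homozygous-wild at the locus).  Away from the
locus both pools hover near 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MARKER, VariantSite, natural_key


def compute_af(site: VariantSite, pool: str) -> float | None:
    """Non-reference allele frequency: nonref / (ref + nonref); None at depth 0."""
    counts = site.counts.get(pool)
    if counts is None:
        return None
    ref, nonref = counts
    if ref < 0 or nonref < 0:
        raise ValueError("negative allele counts")
    total = ref + nonref
    if total == 0:
        return None
    return nonref / total


@dataclass
class AFProfile:
    """Per-site and per-window non-reference allele frequencies for one pool
    on one chromosome."""

    chrom: str
    pool: str
    chrom_length: int
    window_bp: int
    step_bp: int
    sites: pd.DataFrame      # pos, af, depth (usable marker sites only)
    windows: pd.DataFrame    # start, end, n_sites, mean_af, median_af

    def grid_matches(self, other: "AFProfile") -> bool:
        return (
            self.chrom == other.chrom
            and self.chrom_length == other.chrom_length
            and self.window_bp == other.window_bp
            and self.step_bp == other.step_bp
        )


def build_profile(
    sites: list[VariantSite],
    pool: str,
    chrom: str,
    chrom_length: int,
    window_bp: int = 1_000_000,
    step_bp: int = 250_000,
    min_sites: int = 3,
    min_depth: int = 10,
) -> AFProfile:
    """Windowed allele-frequency profile for one pool on one chromosome.

    Only MARKER-origin sites with depth >= ``min_depth`` enter window
    statistics (induced lesions are not informative linkage markers).
    Windows tile [1, chrom_length] at the given step; windows with fewer than
    ``min_sites`` usable sites carry missing summaries.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("need window_bp >= step_bp >= 1")
    rows = []
    for s in sites:
        if s.chrom != chrom or s.origin != MARKER:
            continue
        counts = s.counts.get(pool)
        if counts is None:
            continue
        depth = counts[0] + counts[1]
        if depth < min_depth or depth == 0:
            continue
        rows.append((s.pos, counts[1] / depth, depth))
    rows.sort()
    positions = np.array([r[0] for r in rows], dtype=np.int64)
    if len(np.unique(positions)) != len(positions):
        raise ValueError(f"duplicate marker positions on {chrom}")
    afs = np.array([r[1] for r in rows])
    depths = np.array([r[2] for r in rows], dtype=np.int64)

    starts = np.arange(1, chrom_length + 1, step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp - 1, chrom_length)
    n_sites = np.zeros(len(starts), dtype=np.int64)
    means = np.full(len(starts), np.nan)
    medians = np.full(len(starts), np.nan)
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="right")
    for i in range(len(starts)):
        n = hi[i] - lo[i]
        n_sites[i] = n
        if n >= min_sites:
            window = afs[lo[i] : hi[i]]
            means[i] = window.mean()
            medians[i] = np.median(window)
    return AFProfile(
        chrom=chrom,
        pool=pool,
        chrom_length=chrom_length,
        window_bp=window_bp,
        step_bp=step_bp,
        sites=pd.DataFrame({"pos": positions, "af": afs, "depth": depths}),
        windows=pd.DataFrame(
            {"start": starts, "end": ends, "n_sites": n_sites,
             "mean_af": means, "median_af": medians}
        ),
    )


def build_profiles(
    sites: list[VariantSite],
    pool: str,
    contigs: dict[str, int],
    **kwargs,
) -> dict[str, AFProfile]:
    """One profile per chromosome, in natural chromosome order."""
    return {
        chrom: build_profile(sites, pool, chrom, length, **kwargs)
        for chrom, length in sorted(contigs.items(), key=lambda kv: natural_key(kv[0]))
    }


@dataclass
class CandidateRegion:
    """A run of windows where the mutant pool's allele frequency collapses."""

    chrom: str
    start_bp: int
    end_bp: int
    n_windows: int
    mean_mut_af: float
    mean_wt_af: float
    expansion_bp: int

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


def detect_candidate_region(
    mut: AFProfile,
    wt: AFProfile,
    tau_mut: float = 0.05,
    wt_band: tuple[float, float] = (0.30, 0.85),
    min_run: int = 3,
    pad_bp: int = 2_000_000,
) -> list[CandidateRegion]:
    """Runs of windows where the mutant pool "reaches zero".

    A window is a hit when the mutant-pool window mean is <= ``tau_mut`` and
    the WT-pool window mean lies inside ``wt_band`` (near the locus the WT
    pool is expected around 2/3; ruling out windows where both pools collapse
    guards against shared artefacts).  Maximal runs of at least ``min_run``
    consecutive hits are padded by ``pad_bp`` on both sides and ranked by run
    length, then lower mutant mean, then position.  Missing windows never
    count as hits and break runs.
    """
    if not mut.grid_matches(wt):
        raise ValueError("mutant and WT profiles are on different window grids")
    m = mut.windows["mean_af"].to_numpy()
    w = wt.windows["mean_af"].to_numpy()
    hits = (
        ~np.isnan(m) & ~np.isnan(w)
        & (m <= tau_mut) & (w >= wt_band[0]) & (w <= wt_band[1])
    )
    regions = []
    i = 0
    while i < len(hits):
        if not hits[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(hits) and hits[j + 1]:
            j += 1
        if j - i + 1 >= min_run:
            run = slice(i, j + 1)
            start = int(mut.windows["start"].iloc[i])
            end = int(mut.windows["end"].iloc[j])
            regions.append(
                CandidateRegion(
                    chrom=mut.chrom,
                    start_bp=max(1, start - pad_bp),
                    end_bp=min(mut.chrom_length, end + pad_bp),
                    n_windows=j - i + 1,
                    mean_mut_af=float(np.nanmean(m[run])),
                    mean_wt_af=float(np.nanmean(w[run])),
                    expansion_bp=pad_bp,
                )
            )
        i = j + 1
    regions.sort(key=lambda r: (-r.n_windows, r.mean_mut_af, r.start_bp))
    return regions


def detect_candidate_regions(
    mut_profiles: dict[str, AFProfile],
    wt_profiles: dict[str, AFProfile],
    **kwargs,
) -> list[CandidateRegion]:
    """Detection across all chromosomes, globally ranked."""
    regions = []
    for chrom in mut_profiles:
        regions.extend(
            detect_candidate_region(mut_profiles[chrom], wt_profiles[chrom], **kwargs)
        )
    regions.sort(key=lambda r: (-r.n_windows, r.mean_mut_af,
                                natural_key(r.chrom), r.start_bp))
    return regions


def af_table(profiles: dict[str, dict[str, AFProfile]]) -> pd.DataFrame:
    """Long-format window table: one row per (chrom, window, pool).

    ``profiles`` maps pool name -> chrom -> AFProfile.  Empty windows are
    emitted with missing summaries, not dropped; row order is deterministic
    (natural chromosome order, window start, pool name).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    frames = []
    for pool in sorted(profiles):
        for chrom in sorted(profiles[pool], key=natural_key):
            p = profiles[pool][chrom]
            df = p.windows.copy()
            df.insert(0, "chrom", chrom)
            df.insert(3, "pool", pool)
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"start": "window_start", "end": "window_end"})
    out = out.sort_values(
        ["chrom", "window_start", "pool"],
        key=lambda col: col.map(natural_key) if col.name == "chrom" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    return out[["chrom", "window_start", "window_end", "pool",
                "n_sites", "mean_af", "median_af"]]


def plot_profiles(mut_profiles, wt_profiles, regions=(), path=None):
    """Simple per-chromosome window-mean AF figure (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(mut_profiles)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.6 * len(chroms)),
                             squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        for prof, label, color in ((mut_profiles[chrom], "mutant pool", "#c0392b"),
                                   (wt_profiles[chrom], "WT pool", "#2980b9")):
            w = prof.windows
            ax.plot(w["start"] / 1e6, w["mean_af"], label=label, color=color, lw=1)
        for r in regions:
            if r.chrom == chrom:
                ax.axvspan(r.start_bp / 1e6, r.end_bp / 1e6, color="gold", alpha=0.3)
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("non-ref AF")
        ax.set_title(chrom)
        ax.legend(loc="upper right", fontsize=8)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
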