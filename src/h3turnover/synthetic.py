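"""Seeded synthetic genome annotation and ChIP signal tracks.

The generator emulates the structure of a two-channel tiling-array
histone-turnover experiment in budding yeast: ~250 bp probe tiling,
non-overlapping stranded genes with log-uniform lengths, three biological
replicates per genotype, promoter-peaked / body-protected H3 turnover in
wild type, reversed-polarity turnover in the remodeler-deletion mutant
that diverges from wild type only above a crossover gene length, a
5'-biased H3K4me3 track and a 3'-biased H3K36me3 track whose mutant
profile is shifted 5' and depleted at 3' ends in a length-coupled way,
and genotype-concordant RNA Pol2 tracks for a null concordance check.

All signal is generated on the log2 scale with independent Gaussian probe
noise; every simulator is deterministic for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Gene, Interval, Track, track_from_arrays

WT = "wt"
MUTANT = "mutant"
GENOTYPES = (WT, MUTANT)


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the toy genome and its probe tiling.

    Defaults hold 3000 genes of 0.25-5 kb (log-uniform, so long genes are
    well represented) on 8 chromosomes, with 250 bp probe spacing matching
    the resolution of the tiling arrays being emulated.
    """

    n_chromosomes: int = 8
    chrom_length: int = 1_250_000
    n_genes: int = 3000
    gene_length_range: Tuple[int, int] = (250, 5000)
    min_intergenic: int = 800
    n_ars: int = 40
    probe_spacing: int = 250
    probe_length: int = 51

    def __post_init__(self):
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad gene_length_range {self.gene_length_range}")
        if self.min_intergenic < 0 or self.probe_spacing <= 0 or self.probe_length <= 0:
            raise ValueError("spacing/length parameters must be positive")
        if self.n_chromosomes <= 0 or self.chrom_length <= 0:
            raise ValueError("chromosome layout must be positive")

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class TurnoverModel:
    """Expected log2(Flag-H3 / total-H3) as a function of position in a gene.

    Wild type: turnover peaks just upstream of the coding start
    (``promoter_level``), decays exponentially into the gene body over
    ``five_prime_decay_bp`` down to ``body_floor``, and rises again toward
    a 3'-end level that *decreases* with gene length
    (``wt_3p_slope`` log2 units per log2 of length, capped at
    ``three_prime_cap``). Mutant: the promoter/5' region is slower by
    ``mut_5p_deficit`` while the 3'-end level stops decreasing at
    ``crossover_length`` and stays at ``mut_3p_level``; below the
    crossover the two genotypes share identical 3'-end expectations. The
    mutant 5' deficit never reaches into the terminal
    ``end_exclusion_bp`` of the body, so sub-crossover gene ends are
    genotype-invariant probe by probe.
    """

    promoter_level: float = 1.2
    body_floor: float = -0.6
    five_prime_decay_bp: float = 300.0
    body_entry_drop: float = 0.25
    intergenic_level: float = 0.2
    upstream_decay_bp: float = 400.0
    wt_3p_slope: float = -1.8
    three_prime_decay_bp: float = 400.0
    three_prime_cap: float = 1.0
    crossover_length: int = 1000
    mut_5p_deficit: float = -1.0
    mut_3p_level: float = 0.6
    end_exclusion_bp: int = 500
    noise_sd: float = 0.3
    n_replicates: int = 3

    def __post_init__(self):
        if self.mut_5p_deficit > 0:
            raise ValueError("mut_5p_deficit must be <= 0 (the mutant 5' is slower)")
        if self.wt_3p_slope >= 0:
            raise ValueError("wt_3p_slope must be negative (3' turnover falls with length)")
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise ValueError("noise_sd must be >= 0 and n_replicates >= 1")

    def three_prime_level(self, length: float, genotype: str) -> float:
        """Expected log2 turnover at the very 3' end of a gene of this length."""
        wt_level = self.mut_3p_level + self.wt_3p_slope * math.log2(
            length / self.crossover_length
        )
        wt_level = min(wt_level, self.three_prime_cap)
        if genotype == WT or length <= self.crossover_length:
            return wt_level
        return self.mut_3p_level


@dataclass(frozen=True)
class MarkModel:
    """Expected histone-mark log2 enrichment in metagene-bin coordinates.

    H3K4me3 peaks near the 5' end of the body (bin ``k4_peak_bin``) and
    H3K36me3 near the 3' end (``k36_peak_bin``); both are Gaussian bumps
    in the 30-bin coordinate (10 upstream + 20 body bins). In the mutant
    the K36me3 peak moves ``mut_k36_shift_bins`` bins toward the 5' end
    and its 3'-terminal signal is depleted by ``mut_k36_3p_loss`` log2
    units, scaled up with gene length through ``length_coupling``; K4me3
    is left unchanged (only noise differs), reflecting a mark that is
    minimally affected.
    """

    k4_peak_bin: float = 11.5
    k36_peak_bin: float = 24.0
    k4_amplitude: float = 1.8
    k36_amplitude: float = 1.5
    peak_width_bins: float = 3.0
    mark_floor: float = -0.5
    mut_k36_shift_bins: float = 2.0
    mut_k36_3p_loss: float = 0.25
    length_coupling: float = 1.0
    loss_reference_bp: int = 250
    three_prime_decay_bp: float = 400.0
    noise_sd: float = 0.3

    def __post_init__(self):
        if not self.k4_peak_bin < self.k36_peak_bin:
            raise ValueError("K4me3 must peak 5' of K36me3 (k4_peak_bin < k36_peak_bin)")

    def k36_loss(self, length: float) -> float:
        """Mutant 3'-end K36me3 depletion (log2 units), growing with length."""
        return self.mut_k36_3p_loss * (
            1.0 + self.length_coupling * max(0.0, math.log2(length / self.loss_reference_bp))
        )


@dataclass(frozen=True)
class Pol2Model:
    """Per-gene RNA Pol2 enrichment with a within-gene 5'/3' tilt.

    Each gene draws a log2 mean enrichment and a log2 5'/3' bias once;
    in ``null_mode`` the mutant reuses the wild-type draws so the expected
    genotype difference is zero and only probe noise differs. Between-gene
    spread is deliberately large relative to probe noise, emulating the
    tight genotype concordance of the null the model encodes.
    """

    mean_log2: float = 1.0
    mean_sd_log2: float = 1.2
    bias_log2: float = 0.4
    bias_sd_log2: float = 0.6
    intergenic_level: float = -1.0
    null_mode: bool = True
    noise_sd: float = 0.06


# ---------------------------------------------------------------------------
# annotation


def _pack_chromosome(rng, chrom, lengths, min_intergenic, chrom_length, first_index):
    """Place genes with random intergenic gaps; raise if they cannot fit."""
    n = len(lengths)
    occupied = int(np.sum(lengths)) + (n + 1) * min_intergenic
    if occupied > chrom_length:
        raise ValueError(
            f"infeasible packing on {chrom}: {n} genes plus min_intergenic="
            f"{min_intergenic} need {occupied} bp but chrom_length={chrom_length}"
        )
    slack = chrom_length - occupied
    # split the slack into n+1 random gap extensions
    cuts = np.sort(rng.integers(0, slack + 1, size=n)) if n else np.array([], dtype=int)
    extras = np.diff(np.concatenate(([0], cuts, [slack])))
    genes = []
    pos = 0
    for i, L in enumerate(lengths):
        pos += min_intergenic + int(extras[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene(
                id=f"g{first_index + i:05d}",
                chrom=chrom,
                start=pos,
                end=pos + int(L),
                strand=strand,
            )
        )
        pos += int(L)
    return genes


def generate_annotation(
    spec: GenomeSpec, seed: int
) -> Tuple[List[Gene], List[Interval], List[Interval]]:
    """Generate genes, ARS intervals and the probe tiling for ``spec``.

    Deterministic for a fixed seed. Genes are sorted by coordinate, never
    overlap, and keep at least ``spec.min_intergenic`` bp to each
    neighbour; probes tile every chromosome end to end at
    ``spec.probe_spacing``.
    """
    rng = np.random.default_rng(seed)
    chroms = spec.chrom_names()
    lo, hi = spec.gene_length_range
    lengths = np.exp(
        rng.uniform(math.log(lo), math.log(hi), size=spec.n_genes)
    ).astype(int)
    lengths = np.clip(lengths, lo, hi)
    per_chrom = np.array_split(np.arange(spec.n_genes), spec.n_chromosomes)

    genes: List[Gene] = []
    for chrom, idx in zip(chroms, per_chrom):
        genes.extend(
            _pack_chromosome(
                rng, chrom, lengths[idx], spec.min_intergenic, spec.chrom_length,
                first_index=len(genes),
            )
        )

    # ARS: drop replication-origin intervals into intergenic space
    ars: List[Interval] = []
    ars_per_chrom = np.array_split(np.arange(spec.n_ars), spec.n_chromosomes)
    by_chrom: Dict[str, List[Gene]] = {c: [] for c in chroms}
    for g in genes:
        by_chrom[g.chrom].append(g)
    for chrom, idx in zip(chroms, ars_per_chrom):
        gs = by_chrom[chrom]
        gaps = []
        prev = 0
        for g in gs:
            if g.start - prev >= 120:
                gaps.append((prev, g.start))
            prev = g.end
        if spec.chrom_length - prev >= 120:
            gaps.append((prev, spec.chrom_length))
        for j in idx:
            gap = gaps[int(rng.integers(0, len(gaps)))]
            start = int(rng.integers(gap[0], gap[1] - 100))
            ars.append(Interval(chrom=chrom, start=start, end=start + 100, id=f"ars{j:03d}"))

    # probe tiling, end to end
    probes: List[Interval] = []
    for chrom in chroms:
        starts = np.arange(0, spec.chrom_length, spec.probe_spacing)
        for k, s in enumerate(starts):
            e = min(int(s) + spec.probe_length, spec.chrom_length)
            probes.append(Interval(chrom=chrom, start=int(s), end=e, id=f"{chrom}_p{k}"))
    return genes, ars, probes


def probe_frame(probes: Sequence[Interval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in probes],
            "start": [p.start for p in probes],
            "end": [p.end for p in probes],
        }
    )


# ---------------------------------------------------------------------------
# expected-value fields


def _group_probes(probes: Sequence[Interval]):
    frame = probe_frame(probes)
    frame["mid"] = (frame["start"] + frame["end"]) // 2
    return frame


def _gene_slices(g: Gene, mids: np.ndarray, upstream_reach: int):
    """Probe midpoints inside the gene and in its strand-aware upstream zone."""
    lo = g.start - upstream_reach if g.strand == "+" else g.start
    hi = g.end if g.strand == "+" else g.end + upstream_reach
    i0, i1 = np.searchsorted(mids, [lo, hi])
    m = mids[i0:i1]
    u = np.where(g.strand == "+", g.start - m, m - (g.end - 1)).astype(float)
    d = np.where(g.strand == "+", m - g.start, (g.end - 1) - m).astype(float)
    inside = (m >= g.start) & (m < g.end)
    return slice(i0, i1), u, d, inside


def _turnover_expectation(genes, probe_mid_by_chrom, model: TurnoverModel, genotype: str,
                          gain_scale=None):
    """Noise-free expected turnover per probe.

    Gene bodies are assigned directly (genes never overlap); intergenic
    probes take the maximum over the upstream/promoter contributions of
    neighbouring genes (divergent promoters) with the intergenic level as
    far-field floor. A gene body is never diluted by a neighbour's
    promoter tail.
    """
    expect = {
        chrom: np.full(len(mids), model.intergenic_level)
        for chrom, mids in probe_mid_by_chrom.items()
    }
    in_gene = {chrom: np.zeros(len(mids), bool) for chrom, mids in probe_mid_by_chrom.items()}
    a5_wt = model.promoter_level - model.body_entry_drop - model.body_floor
    deficit = model.mut_5p_deficit if genotype == MUTANT else 0.0
    p_level = model.promoter_level + deficit

    for g in genes:
        mids = probe_mid_by_chrom[g.chrom]
        sl, u, d, inside = _gene_slices(g, mids, upstream_reach=2500)
        L = g.length
        vals = expect[g.chrom][sl]
        flags = in_gene[g.chrom][sl]

        ups = ~inside & (u > 0) & ~flags
        upstream_val = model.intergenic_level + (
            p_level - model.intergenic_level
        ) * np.exp(-u / model.upstream_decay_bp)
        vals[ups] = np.maximum(vals[ups], upstream_val[ups])

        if inside.any():
            di = d[inside]
            tp = model.three_prime_level(L, genotype)
            if gain_scale is not None and genotype == MUTANT:
                # transcription-coupled mutant effect: scale the 3'-end
                # divergence from wild type per gene
                tp_wt = model.three_prime_level(L, WT)
                tp = tp_wt + (tp - tp_wt) * float(gain_scale.get(g.id, 1.0))
            a3 = tp - model.body_floor
            a5 = np.where(di < max(0, L - model.end_exclusion_bp), a5_wt + deficit, a5_wt)
            five = a5 * np.exp(-di / model.five_prime_decay_bp)
            three = a3 * np.exp(-((L - 1) - di) / model.three_prime_decay_bp)
            vals[inside] = model.body_floor + np.maximum(five, three)
            flags[inside] = True

        expect[g.chrom][sl] = vals
        in_gene[g.chrom][sl] = flags
    return expect


def _assemble_track(frame, expect_by_chrom, noise_sd, rng, **meta) -> Track:
    values = np.empty(len(frame))
    for chrom, sub in frame.groupby("chrom", sort=False):
        values[sub.index.to_numpy()] = expect_by_chrom[chrom]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return track_from_arrays(
        frame["chrom"], frame["start"], frame["end"], values, **meta
    )


def simulate_turnover(
    genes: Sequence[Gene],
    probes: Sequence[Interval],
    model: TurnoverModel,
    genotype: str,
    seed: int,
    gain_scale=None,
) -> List[Track]:
    """Simulate one log2(Flag/total) turnover track per replicate.

    ``gain_scale`` optionally maps gene id -> multiplier on the mutant's
    3'-end divergence from wild type, e.g. to couple the mutant effect to
    transcription level; wild type is unaffected.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rng = np.random.default_rng(seed)
    frame = _group_probes(probes)
    mid_by_chrom = {c: s["mid"].to_numpy() for c, s in frame.groupby("chrom", sort=False)}
    expect = _turnover_expectation(genes, mid_by_chrom, model, genotype, gain_scale)
    return [
        _assemble_track(
            frame, expect, model.noise_sd, rng,
            label="turnover", genotype=genotype, replicate=r + 1,
        )
        for r in range(model.n_replicates)
    ]


def _mark_expectation(genes, probe_mid_by_chrom, model: MarkModel, mark: str, genotype: str):
    expect = {
        chrom: np.full(len(mids), model.mark_floor)
        for chrom, mids in probe_mid_by_chrom.items()
    }
    if mark == "k4":
        peak, amp = model.k4_peak_bin, model.k4_amplitude
        shift = 0.0
    elif mark == "k36":
        peak, amp = model.k36_peak_bin, model.k36_amplitude
        shift = model.mut_k36_shift_bins if genotype == MUTANT else 0.0
    else:
        raise ValueError(f"unknown mark {mark!r}; expected 'k4' or 'k36'")
    in_gene = {chrom: np.zeros(len(mids), bool) for chrom, mids in probe_mid_by_chrom.items()}
    for g in genes:
        mids = probe_mid_by_chrom[g.chrom]
        sl, u, d, inside = _gene_slices(g, mids, upstream_reach=500)
        L = g.length
        vals = expect[g.chrom][sl]
        flags = in_gene[g.chrom][sl]
        # continuous 30-bin coordinate: upstream [0,10), body [10,30)
        b_up = (500.0 - np.clip(u, 0, 500)) / 50.0
        b = np.where(inside, 10.0 + 20.0 * d / L, b_up)
        bump = amp * np.exp(-((b - (peak - shift)) ** 2) / (2 * model.peak_width_bins**2))
        contrib = model.mark_floor + bump
        if mark == "k36" and genotype == MUTANT:
            loss = model.k36_loss(L)
            contrib = contrib - np.where(
                inside, loss * np.exp(-((L - 1) - d) / model.three_prime_decay_bp), 0.0
            )
        ups = ~inside & (u > 0) & (u <= 500) & ~flags
        vals[ups] = np.maximum(vals[ups], contrib[ups])
        vals[inside] = contrib[inside]
        flags[inside] = True
    return expect


def simulate_marks(
    genes: Sequence[Gene],
    probes: Sequence[Interval],
    model: MarkModel,
    genotype: str,
    seed: int,
) -> Tuple[Track, Track]:
    """Simulate (H3K4me3, H3K36me3) log2 enrichment tracks for one genotype."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rng = np.random.default_rng(seed)
    frame = _group_probes(probes)
    mid_by_chrom = {c: s["mid"].to_numpy() for c, s in frame.groupby("chrom", sort=False)}
    k4 = _assemble_track(
        frame, _mark_expectation(genes, mid_by_chrom, model, "k4", genotype),
        model.noise_sd, rng, label="k4me3", genotype=genotype,
    )
    k36 = _assemble_track(
        frame, _mark_expectation(genes, mid_by_chrom, model, "k36", genotype),
        model.noise_sd, rng, label="k36me3", genotype=genotype,
    )
    return k4, k36


def simulate_pol2(
    genes: Sequence[Gene],
    probes: Sequence[Interval],
    model: Pol2Model,
    seed: int,
) -> Tuple[Track, Track]:
    """Simulate (wild-type, mutant) RNA Pol2 log2 enrichment tracks.

    In ``null_mode`` the two genotypes share identical per-gene
    expectations (the same gene-level draws), so any fitted genotype
    difference reflects probe noise alone.
    """
    rng = np.random.default_rng(seed)
    frame = _group_probes(probes)
    mid_by_chrom = {c: s["mid"].to_numpy() for c, s in frame.groupby("chrom", sort=False)}

    means = rng.normal(model.mean_log2, model.mean_sd_log2, size=len(genes))
    biases = rng.normal(model.bias_log2, model.bias_sd_log2, size=len(genes))
    if not model.null_mode:
        means_mut = rng.normal(model.mean_log2, model.mean_sd_log2, size=len(genes))
        biases_mut = rng.normal(model.bias_log2, model.bias_sd_log2, size=len(genes))
    else:
        means_mut, biases_mut = means, biases

    def build(mean_arr, bias_arr, genotype):
        expect = {
            chrom: np.full(len(mids), model.intergenic_level)
            for chrom, mids in mid_by_chrom.items()
        }
        for g, mg, bg in zip(genes, mean_arr, bias_arr):
            mids = mid_by_chrom[g.chrom]
            i0, i1 = np.searchsorted(mids, [g.start, g.end])
            m = mids[i0:i1]
            d = np.where(g.strand == "+", m - g.start, (g.end - 1) - m).astype(float)
            expect[g.chrom][i0:i1] = mg + bg * (0.5 - d / g.length)
        return expect

    wt = _assemble_track(
        frame, build(means, biases, WT), model.noise_sd, rng, label="pol2", genotype=WT
    )
    mut = _assemble_track(
        frame, build(means_mut, biases_mut, MUTANT), model.noise_sd, rng,
        label="pol2", genotype=MUTANT,
    )
    return wt, mut


def expression_table(genes: Sequence[Gene], pol2_wt: Track, seed: int,
                     noise_sd: float = 0.2) -> pd.DataFrame:
    """Per-gene expression log2(mut/wt) with no length or transcription coupling.

    Emulates the observation that the mutant's expression changes do not
    correlate with transcript length or transcription frequency: the
    log2 fold changes are pure noise around zero.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "id": [g.id for g in genes],
            "length": [g.length for g in genes],
            "expression_log2fc": rng.normal(0.0, noise_sd, size=len(genes)),
        }
    )


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_ip_fraction: float,
    input_ct: float,
    noise_sd_ct: float = 0.0,
    seed: int = 0,
) -> Tuple[float, float]:
    """Generate (input_ct, ip_ct) for a known IP/Input fraction.

    Inverts the perfect-doubling enrichment formula IP/Input =
    2^(InputCt - IPCt): with zero noise, ip_ct = input_ct -
    log2(true_ip_fraction).
    """
    if not (true_ip_fraction > 0):
        raise ValueError("true_ip_fraction must be positive")
    rng = np.random.default_rng(seed)
    ip_ct = input_ct - math.log2(true_ip_fraction)
    if noise_sd_ct > 0:
        ip_ct += rng.normal(0.0, noise_sd_ct)
    return float(input_ct), float(ip_ct)
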