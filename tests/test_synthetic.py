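import dataclasses
import math

import numpy as np
import pytest

from h3turnover import (
    GenomeSpec, MarkModel, Pol2Model, TurnoverModel, aggregate_metagene,
    classify_probes, generate_annotation, simulate_marks, simulate_pol2,
    simulate_turnover, write_intervals,
)
from h3turnover.elements import ElementClass
from h3turnover.windows import THREE_PRIME, end_average
from h3turnover.metagene import _TrackIndex


class TestGenerateAnnotation:
    def test_gene_count_conserved(self, small_spec):
        genes, _, _ = generate_annotation(dataclasses.replace(small_spec, n_genes=50), 3)
        assert len(genes) == 50

    def test_byte_identical_for_same_seed(self, small_spec, tmp_path):
        paths = []
        for name in ("a.bed", "b.bed"):
            genes, ars, _ = generate_annotation(small_spec, 11)
            write_intervals(genes, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_lengths_within_range(self, small_spec):
        genes, _, _ = generate_annotation(small_spec, 5)
        lo, hi = small_spec.gene_length_range
        assert all(lo <= g.length <= hi for g in genes)

    def test_genes_sorted_nonoverlapping_with_spacing(self, small_spec, small_annotation):
        genes, _, _ = small_annotation
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            assert gs == sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert b.start - a.end >= small_spec.min_intergenic

    def test_probe_tiling_covers_chromosomes(self, small_spec, small_annotation):
        _, _, probes = small_annotation
        expected = small_spec.n_chromosomes * math.ceil(
            small_spec.chrom_length / small_spec.probe_spacing
        )
        assert len(probes) == expected
        for chrom in small_spec.chrom_names():
            ends = [p.end for p in probes if p.chrom == chrom]
            starts = [p.start for p in probes if p.chrom == chrom]
            assert min(starts) == 0
            assert small_spec.chrom_length - max(starts) <= small_spec.probe_spacing

    def test_infeasible_packing_names_constraint(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=5_000, n_genes=20,
                          gene_length_range=(300, 500), min_intergenic=700, n_ars=1)
        with pytest.raises(ValueError, match="infeasible packing.*min_intergenic"):
            generate_annotation(spec, 1)


@pytest.fixture(scope="module")
def noiseless(small_annotation):
    genes, _, probes = small_annotation
    model = dataclasses.replace(TurnoverModel(), noise_sd=0.0, n_replicates=1)
    wt = simulate_turnover(genes, probes, model, "wt", 1)[0]
    mut = simulate_turnover(genes, probes, model, "mutant", 2)[0]
    return genes, probes, model, wt, mut


class TestSimulateTurnover:
    def test_replicate_count_matches_model(self, small_annotation):
        genes, _, probes = small_annotation
        tracks = simulate_turnover(genes, probes, TurnoverModel(), "wt", 1)
        assert len(tracks) == 3
        assert [t.replicate for t in tracks] == [1, 2, 3]

    def test_unknown_genotype_rejected(self, small_annotation):
        genes, _, probes = small_annotation
        with pytest.raises(ValueError, match="genotype"):
            simulate_turnover(genes, probes, TurnoverModel(), "het", 1)

    def test_seed_determinism_and_replicate_independence(self, small_annotation):
        genes, _, probes = small_annotation
        a = simulate_turnover(genes, probes, TurnoverModel(), "wt", 9)
        b = simulate_turnover(genes, probes, TurnoverModel(), "wt", 9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.values, tb.values)
        assert not np.allclose(a[0].values, a[1].values)

    def test_noiseless_promoter_exceeds_mid_cds(self, noiseless):
        genes, probes, _, wt, _ = noiseless
        classes = classify_probes(probes, genes)
        labels = np.array([c.value for c in classes])
        values = wt.values
        promoterish = np.isin(labels, [ElementClass.TSS.value, ElementClass.PROMOTER.value])
        mid = labels == ElementClass.MID_CDS.value
        assert values[promoterish].mean() > values[mid].mean()

    def test_short_gene_three_prime_ends_identical_probe_by_probe(self, noiseless):
        genes, probes, model, wt, mut = noiseless
        iw, im = _TrackIndex(wt), _TrackIndex(mut)
        short = [g for g in genes if g.length <= model.crossover_length]
        assert short, "fixture needs sub-crossover genes"
        for g in short:
            w = min(500, g.length)
            mids_w, vals_w = iw.window(g.chrom, g.start, g.end)
            mids_m, vals_m = im.window(g.chrom, g.start, g.end)
            off = mids_w - g.start if g.strand == "+" else (g.end - 1) - mids_w
            sel = off >= g.length - w
            np.testing.assert_allclose(vals_w[sel], vals_m[sel], atol=1e-12)

    def test_long_gene_three_prime_diverges(self, noiseless):
        genes, _, model, wt, mut = noiseless
        iw, im = _TrackIndex(wt), _TrackIndex(mut)
        for g in genes:
            if g.length > 2 * model.crossover_length:
                vw = end_average(iw, g, THREE_PRIME)
                vm = end_average(im, g, THREE_PRIME)
                if vw is None or vm is None:
                    continue
                assert vm > vw


class TestSimulateMarks:
    def test_seed_determinism(self, small_annotation):
        genes, _, probes = small_annotation
        a = simulate_marks(genes, probes, MarkModel(), "wt", 3)
        b = simulate_marks(genes, probes, MarkModel(), "wt", 3)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.values, tb.values)

    def test_k4_peaks_upstream_of_k36(self, small_annotation):
        genes, _, probes = small_annotation
        model = dataclasses.replace(MarkModel(), noise_sd=0.0)
        k4, k36 = simulate_marks(genes, probes, model, "wt", 1)
        p4 = aggregate_metagene(k4, genes)
        p36 = aggregate_metagene(k36, genes)
        assert np.nanargmax(p4.bins) < np.nanargmax(p36.bins)

    def test_mutant_k36_lost_at_three_prime_of_longer_genes(self, small_annotation):
        genes, _, probes = small_annotation
        model = dataclasses.replace(MarkModel(), noise_sd=0.0)
        _, k36_wt = simulate_marks(genes, probes, model, "wt", 1)
        _, k36_mut = simulate_marks(genes, probes, model, "mutant", 2)
        iw, im = _TrackIndex(k36_wt), _TrackIndex(k36_mut)
        median_len = np.median([g.length for g in genes])
        deltas = []
        for g in genes:
            if g.length <= median_len:
                continue
            vw = end_average(iw, g, THREE_PRIME)
            vm = end_average(im, g, THREE_PRIME)
            if vw is not None and vm is not None:
                deltas.append(vm - vw)
        assert deltas and all(d < 0 for d in deltas)


class TestSimulatePol2:
    def test_null_mode_zero_noise_tracks_identical(self, small_annotation):
        genes, _, probes = small_annotation
        model = dataclasses.replace(Pol2Model(), noise_sd=0.0)
        wt, mut = simulate_pol2(genes, probes, model, 5)
        np.testing.assert_array_equal(wt.values, mut.values)

    def test_non_null_mode_differs(self, small_annotation):
        genes, _, probes = small_annotation
        model = dataclasses.replace(Pol2Model(), noise_sd=0.0, null_mode=False)
        wt, mut = simulate_pol2(genes, probes, model, 5)
        assert not np.allclose(wt.values, mut.values)

    def test_seed_determinism(self, small_annotation):
        genes, _, probes = small_annotation
        a = simulate_pol2(genes, probes, Pol2Model(), 8)
        b = simulate_pol2(genes, probes, Pol2Model(), 8)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)
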