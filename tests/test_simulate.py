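import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from tagwinnow.errors import ParameterError
from tagwinnow.simulate import (
    FragmentDist,
    SimulationParams,
    simulate_alignments,
    simulate_catalogue,
    simulate_counts,
)


def _binomial_bounds(p, n, z=2.5758):  # 99% two-sided normal bounds
    half = z * math.sqrt(p * (1 - p) / n)
    return p - half, p + half


class TestCatalogue:
    def test_constant_fragments_share_one_accession(self):
        params = SimulationParams(
            n_transcripts=1, fragments_per_transcript=FragmentDist("constant", 3), seed=1
        )
        contigs, truth = simulate_catalogue(params)
        assert len(contigs) == 3
        assert contigs["accession"].nunique() == 1
        assert truth.contig_map["accession"].nunique() == 1

    def test_every_contig_maps_to_exactly_one_transcript(self, small_catalogue):
        contigs, truth = small_catalogue
        assert truth.contig_map["contig_id"].is_unique
        assert set(truth.contig_map["accession"]) <= set(truth.transcripts.index)

    def test_length_distribution_matches_published_assembly_shape(self):
        params = SimulationParams(
            n_transcripts=10_000,
            fragments_per_transcript=FragmentDist("constant", 1),
            seed=3,
        )
        contigs, _ = simulate_catalogue(params)
        median = contigs["length_bp"].median()
        assert 391 * 0.9 <= median <= 391 * 1.1
        assert contigs["length_bp"].min() >= 101

    def test_same_seed_gives_identical_catalogue(self, small_params):
        a, _ = simulate_catalogue(small_params)
        b, _ = simulate_catalogue(small_params)
        pd.testing.assert_frame_equal(a, b)

    def test_true_fold_of_up_transcripts_equals_effect_fold_exactly(self):
        params = SimulationParams(n_transcripts=500, effect_fold=5.0, seed=11)
        _, truth = simulate_catalogue(params)
        for t in ("bacterial", "fungal"):
            up = truth.transcripts[truth.transcripts[f"reg_{t}"] == "up"]
            assert len(up) > 0
            # the applied fold is exactly 5x the control expression
            assert np.all(up[f"expr_{t}"].to_numpy() == up["expr_control"].to_numpy() * 5.0)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_transcripts", 0),
            ("treatments", ("control",)),
            ("sd_log_expression", 0.0),
            ("frac_up", 1.2),
            ("frac_down", -0.1),
            ("effect_fold", 2.0),
            ("dispersion", -0.5),
            ("frac_ambiguous_reads", 1.5),
        ],
    )
    def test_invalid_params_name_the_field(self, field, value):
        params = dataclasses.replace(SimulationParams(), **{field: value})
        with pytest.raises(ParameterError, match=field.split("_")[0]):
            params.validate()


class TestCounts:
    def test_zero_expression_gives_all_zero_row(self, small_catalogue, small_params):
        contigs, truth = small_catalogue
        victim = truth.contig_expression.index[0]
        truth.contig_expression.loc[victim] = 0.0
        counts = simulate_counts(contigs, truth, small_params)
        assert (counts.loc[victim] == 0).all()

    def test_poisson_totals_match_expectation(self):
        # dispersion 0: the control column total is Poisson(depth)
        params = SimulationParams(
            n_transcripts=200,
            fragments_per_transcript=FragmentDist("constant", 1),
            fragment_corr_noise=0.0,
            dispersion=0.0,
            depth_per_treatment=50_000,
            seed=5,
        )
        contigs, truth = simulate_catalogue(params)
        counts = simulate_counts(contigs, truth, params)
        total = counts["control"].sum()
        assert abs(total - 50_000) < 3 * math.sqrt(50_000)

    def test_cell_expectation_scales_with_true_expression(self):
        # one transcript, one fragment: its control count IS the depth
        params = SimulationParams(
            n_transcripts=1,
            fragments_per_transcript=FragmentDist("constant", 1),
            fragment_corr_noise=0.0,
            dispersion=0.0,
            frac_up=0.0,
            frac_down=0.0,
            depth_per_treatment=10_000,
            seed=6,
        )
        contigs, truth = simulate_catalogue(params)
        counts = simulate_counts(contigs, truth, params)
        for t in params.treatments:
            assert abs(counts[t].iloc[0] - 10_000) < 3 * math.sqrt(10_000)

    def test_same_seed_gives_identical_matrix(self, small_catalogue, small_params):
        contigs, truth = small_catalogue
        a = simulate_counts(contigs, truth, small_params)
        b = simulate_counts(contigs, truth, small_params)
        pd.testing.assert_frame_equal(a, b)

    def test_overdispersion_inflates_variance(self):
        base = SimulationParams(
            n_transcripts=400,
            fragments_per_transcript=FragmentDist("constant", 1),
            sd_log_expression=1e-9,  # near-equal expression across transcripts
            fragment_corr_noise=0.0,
            frac_up=0.0,
            frac_down=0.0,
            depth_per_treatment=400 * 100,
            seed=8,
        )
        contigs, truth = simulate_catalogue(base)
        poisson = simulate_counts(contigs, truth, dataclasses.replace(base, dispersion=0.0))
        overdisp = simulate_counts(contigs, truth, dataclasses.replace(base, dispersion=0.5))
        # scaled residual (c - mu)^2 / mu averages ~1 for Poisson and
        # ~1 + d*mu (tens) under gamma-mixed overdispersion
        lam = 400 * 100 / truth.contig_expression["control"].sum()
        mu = truth.contig_expression["control"].to_numpy() * lam
        z_poisson = ((poisson["control"].to_numpy() - mu) ** 2 / mu).mean()
        z_overdisp = ((overdisp["control"].to_numpy() - mu) ** 2 / mu).mean()
        assert z_poisson < 2.0
        assert z_overdisp > 10.0


class TestAlignments:
    def test_no_ambiguity_means_single_accession_per_read(self, small_catalogue, small_params):
        contigs, truth = small_catalogue
        params = dataclasses.replace(small_params, frac_ambiguous_reads=0.0)
        aln = simulate_alignments(contigs, truth, params)
        acc = truth.contig_map.set_index("contig_id")["accession"]
        per_read = aln.assign(acc=aln["contig_id"].map(acc)).groupby("read_id")["acc"].nunique()
        assert (per_read == 1).all()
        assert truth.ambiguous_read_ids == set()

    def test_ambiguous_fraction_within_binomial_bounds(self):
        params = SimulationParams(
            n_transcripts=100,
            fragments_per_transcript=FragmentDist("constant", 2),
            depth_per_treatment=10_000,
            treatments=("control", "bacterial"),
            frac_ambiguous_reads=0.2,
            seed=13,
        )
        contigs, truth = simulate_catalogue(params)
        aln = simulate_alignments(contigs, truth, params)
        n_reads = aln["read_id"].nunique()
        frac = len(truth.ambiguous_read_ids) / n_reads
        lo, hi = _binomial_bounds(0.2, n_reads)
        assert lo <= frac <= hi

    def test_zero_depth_gives_empty_table(self, small_catalogue, small_params):
        contigs, truth = small_catalogue
        params = dataclasses.replace(small_params, depth_per_treatment=0.0)
        aln = simulate_alignments(contigs, truth, params)
        assert aln.empty

    def test_per_contig_hit_totals_track_expression(self):
        params = SimulationParams(
            n_transcripts=50,
            fragments_per_transcript=FragmentDist("constant", 1),
            fragment_corr_noise=0.0,
            dispersion=0.0,
            frac_ambiguous_reads=0.0,
            depth_per_treatment=50_000,
            seed=17,
        )
        contigs, truth = simulate_catalogue(params)
        aln = simulate_alignments(contigs, truth, params)
        control = aln[aln["treatment"] == "control"]
        observed = control.groupby("contig_id").size()
        lam = 50_000 / truth.contig_expression["control"].sum()
        expected = truth.contig_expression["control"] * lam
        # every contig's hit count within 4 sigma of its Poisson expectation
        resid = (observed.reindex(expected.index, fill_value=0) - expected) / np.sqrt(expected)
        assert np.abs(resid).max() < 4.0

    def test_same_seed_gives_identical_alignments(self, small_catalogue, small_params):
        contigs, truth = small_catalogue
        a = simulate_alignments(contigs, truth, small_params)
        b = simulate_alignments(contigs, truth, small_params)
        pd.testing.assert_frame_equal(a, b)
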