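import math

import numpy as np
import pytest

from bimotif import (
    BackgroundCounts,
    BipartiteSpec,
    CountMatrix,
    ModelState,
    MotifModel,
    Placement,
    background_counts,
    count_sites,
    delta_ic_remove_add,
    export_matrix,
    information_content,
    read_matrix,
    reference_ic,
    site_log_odds,
    to_model,
)
from conftest import random_placements, random_records


class TestSpecValidation:
    def test_one_block_requires_zero_gap(self):
        with pytest.raises(ValueError):
            BipartiteSpec(22, 0, 1, 3)
        spec = BipartiteSpec(22, 0, 0, 0)
        assert spec.n_columns == 22

    def test_di_needs_two_bases_per_block(self):
        with pytest.raises(ValueError):
            BipartiteSpec(2, 1, 0, 2, kind="di")
        assert BipartiteSpec(2, 0, 0, 0, kind="di").n_columns == 1

    def test_di_column_count_skips_junction_and_gap(self):
        assert BipartiteSpec(4, 8, 2, 5, kind="di").n_columns == 3 + 7


class TestCounting:
    def test_mono_tally_of_identical_sites(self):
        spec = BipartiteSpec(2, 0, 0, 0)
        seqs = ["ACGG", "ACTT", "TACG"]
        pls = [Placement(0, 0, 0), Placement(1, 0, 0), Placement(2, 1, 0)]
        cm = count_sites(seqs, pls, spec)
        assert cm.counts[0].tolist() == [3, 0, 0, 0]
        assert cm.counts[1].tolist() == [0, 3, 0, 0]

    def test_di_tally_of_identical_sites(self):
        spec = BipartiteSpec(2, 0, 0, 0, kind="di")
        seqs = ["ACGG", "ACTT", "TACG"]
        pls = [Placement(0, 0, 0), Placement(1, 0, 0), Placement(2, 1, 0)]
        cm = count_sites(seqs, pls, spec)
        assert cm.counts.shape == (1, 16)
        assert cm.counts[0, 1] == 3  # AC
        assert cm.counts[0].sum() == 3

    def test_di_junction_pair_excluded(self):
        # site "AC g TG": di columns are AC and TG only, never the C-T junction
        spec = BipartiteSpec(2, 2, 1, 1, kind="di")
        cm = count_sites(["ACGTG"], [Placement(0, 0, 1)], spec)
        assert cm.counts.shape == (2, 16)
        assert cm.counts[0, 1] == 1  # AC
        assert cm.counts[1, 4 * 3 + 2] == 1  # TG
        assert cm.counts.sum() == 2  # no CT/CG junction pair anywhere

    def test_background_with_no_placements_is_whole_sequence(self):
        spec = BipartiteSpec(2, 0, 0, 0)
        bg = background_counts(["ACGT"], [], spec)
        assert bg.g.tolist() == [1, 1, 1, 1]
        assert bg.n == 4

    def test_background_empty_when_block_covers_everything(self):
        spec = BipartiteSpec(4, 0, 0, 0)
        bg = background_counts(["AAAA"], [Placement(0, 0, 0)], spec)
        assert bg.n == 0

    def test_di_background_excludes_pairs_touching_blocks(self):
        # block covers positions 2-3 of AACCGG
        spec = BipartiteSpec(2, 0, 0, 0)
        pls = [Placement(0, 2, 0)]
        bg = background_counts(["AACCGG"], pls, spec)
        assert bg.g.tolist() == [2, 0, 2, 0]
        assert bg.n == 4
        spec_di = BipartiteSpec(2, 0, 0, 0, kind="di")
        bg_di = background_counts(["AACCGG"], pls, spec_di)
        assert bg_di.n == 2
        assert bg_di.g[0] == 1  # AA
        assert bg_di.g[4 * 2 + 2] == 1  # GG

    def test_gap_positions_count_as_background(self):
        spec = BipartiteSpec(2, 2, 2, 2)
        bg = background_counts(["AATTCCGG"], [Placement(0, 0, 2)], spec)
        # blocks cover 0-1 and 4-5; gap TT and tail GG are background
        assert bg.n == 4
        assert bg.g[3] == 2 and bg.g[2] == 2

    def test_out_of_bounds_placement_rejected(self):
        spec = BipartiteSpec(3, 3, 1, 2)
        with pytest.raises(ValueError):
            count_sites(["ACGTACG"], [Placement(0, 1, 1)], spec)

    def test_mono_count_conservation(self, rng, small_spec):
        recs = random_records(rng, 6, 25)
        pls = random_placements(rng, recs, small_spec)
        cm = count_sites(recs, pls, small_spec)
        bg = background_counts(recs, pls, small_spec)
        assert cm.counts.sum() + bg.g.sum() == pytest.approx(6 * 25)


class TestModel:
    def test_pseudo_count_formula_mono(self):
        cm = CountMatrix("mono", np.array([[3.0, 0, 0, 0]]), 3.0)
        bg = BackgroundCounts(np.zeros(4), 0.0)
        m = to_model(cm, bg, beta=1.0)
        assert m.probs[0, 0] == pytest.approx(0.8125, abs=1e-12)
        assert m.probs[0, 1] == pytest.approx(0.0625, abs=1e-12)
        assert m.background.tolist() == [0.25] * 4

    def test_pseudo_count_formula_di(self):
        counts = np.zeros((1, 16))
        counts[0, 1] = 2.0  # AC
        m = to_model(
            CountMatrix("di", counts, 2.0), BackgroundCounts(np.zeros(16), 0.0)
        )
        assert m.probs[0, 1] == pytest.approx((2 + 1 / 16) / 3, abs=1e-12)

    def test_columns_and_background_normalized(self, rng, small_spec):
        recs = random_records(rng, 8, 30)
        pls = random_placements(rng, recs, small_spec)
        m = to_model(
            count_sites(recs, pls, small_spec),
            background_counts(recs, pls, small_spec),
        )
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)
        assert m.background.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_model_error(self):
        from bimotif import EmptyModelError

        with pytest.raises(EmptyModelError):
            to_model(
                CountMatrix("mono", np.zeros((1, 4)), 0.0),
                BackgroundCounts(np.zeros(4), 0.0),
                beta=0.0,
            )


class TestInformationContent:
    def test_zero_when_motif_equals_background(self):
        b = np.array([0.1, 0.2, 0.3, 0.4])
        m = MotifModel("mono", np.tile(b, (3, 1)), b, beta=1.0)
        assert information_content(m) == pytest.approx(0.0, abs=1e-12)

    def test_fully_conserved_column_against_uniform(self):
        m = MotifModel(
            "mono", np.array([[1.0, 0, 0, 0]]), np.full(4, 0.25), beta=0.0
        )
        assert information_content(m) == pytest.approx(-2.0, abs=1e-12)

    def test_matches_term_by_term_summation(self, rng):
        probs = rng.dirichlet(np.ones(4), size=2)
        bg = rng.dirichlet(np.ones(4))
        m = MotifModel("mono", probs, bg, beta=1.0)
        expected = sum(
            -probs[i, x] * math.log2(probs[i, x] / bg[x])
            for i in range(2)
            for x in range(4)
        )
        assert information_content(m) == pytest.approx(expected, abs=1e-12)

    def test_concentration_beats_background(self):
        # sharpening any column away from the background strictly lowers IC
        b = np.full(4, 0.25)
        flat = MotifModel("mono", np.tile(b, (1, 1)), b, beta=1.0)
        sharp = MotifModel("mono", np.array([[0.7, 0.1, 0.1, 0.1]]), b, beta=1.0)
        assert information_content(sharp) < information_content(flat)


class TestSiteLogOdds:
    def test_zero_when_site_matches_background(self):
        b = np.full(4, 0.25)
        spec = BipartiteSpec(2, 0, 0, 0)
        m = MotifModel("mono", np.tile(b, (2, 1)), b, beta=1.0, spec=spec)
        assert site_log_odds(m, "ACGT", 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_consensus_closed_form(self):
        spec = BipartiteSpec(1, 0, 0, 0)
        m = MotifModel(
            "mono", np.array([[0.8125, 0.0625, 0.0625, 0.0625]]),
            np.full(4, 0.25), beta=1.0, spec=spec,
        )
        assert site_log_odds(m, "AGGT", 0, 0) == pytest.approx(
            math.log2(0.8125 / 0.25), abs=1e-9
        )

    def test_matches_per_column_sum(self, rng, small_spec):
        recs = random_records(rng, 6, 25)
        pls = random_placements(rng, recs, small_spec)
        m = to_model(
            count_sites(recs, pls, small_spec),
            background_counts(recs, pls, small_spec),
        )
        m.spec = small_spec
        from bimotif.alphabet import encode
        from bimotif.matrices import site_symbol_codes

        p = pls[0]
        codes = site_symbol_codes(encode(recs[0].seq), p, small_spec)
        expected = sum(
            math.log2(m.probs[i, c] / m.background[c]) for i, c in enumerate(codes)
        )
        got = site_log_odds(m, recs[0].seq, p.left_start, p.gap)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds_rejected(self, small_spec):
        m = MotifModel(
            "mono", np.full((6, 4), 0.25), np.full(4, 0.25), beta=1.0, spec=small_spec
        )
        with pytest.raises(ValueError):
            site_log_odds(m, "ACGTACG", 3, 2)


class TestIncrementalState:
    @pytest.mark.parametrize("kind", ["mono", "di"])
    def test_swap_matches_full_recompute(self, rng, kind):
        spec = BipartiteSpec(3, 3, 1, 2, kind=kind)
        recs = random_records(rng, 10, 24, with_n=True)
        pls = random_placements(rng, recs, spec)
        state = ModelState.from_placements(recs, pls, spec)
        current = list(pls)
        for _ in range(200):
            i = int(rng.integers(len(recs)))
            gap = int(rng.integers(spec.gap_min, spec.gap_max + 1))
            start = int(rng.integers(len(recs[i]) - spec.span(gap) + 1))
            new = Placement(seq_index=i, left_start=start, gap=gap)
            before = reference_ic(recs, current, spec)
            delta = delta_ic_remove_add(state, current[i], new)
            current[i] = new
            after = reference_ic(recs, current, spec)
            assert delta == pytest.approx(after - before, abs=1e-9)
            assert state.ic() == pytest.approx(after, abs=1e-9)

    def test_noop_swap_is_zero(self, rng, small_spec):
        recs = random_records(rng, 5, 20)
        pls = random_placements(rng, recs, small_spec)
        state = ModelState.from_placements(recs, pls, small_spec)
        assert delta_ic_remove_add(state, pls[0], pls[0]) == pytest.approx(0, abs=1e-12)

    def test_remove_then_readd_nets_zero(self, rng, small_spec):
        recs = random_records(rng, 5, 20)
        pls = random_placements(rng, recs, small_spec)
        state = ModelState.from_placements(recs, pls, small_spec)
        d1 = delta_ic_remove_add(state, pls[0], None)
        d2 = delta_ic_remove_add(state, None, pls[0])
        assert d1 + d2 == pytest.approx(0.0, abs=1e-9)


class TestMatrixExport:
    @pytest.mark.parametrize(
        "spec",
        [
            BipartiteSpec(6, 6, 2, 4),
            BipartiteSpec(4, 8, 1, 1, kind="di"),
            BipartiteSpec(12, 0, 0, 0),
        ],
    )
    def test_round_trip_exact(self, tmp_path, rng, spec):
        recs = random_records(rng, 6, 40)
        pls = random_placements(rng, recs, spec)
        m = to_model(count_sites(recs, pls, spec), background_counts(recs, pls, spec))
        path = tmp_path / "m.tsv"
        export_matrix(m, path)
        back = read_matrix(path)
        assert back.kind == m.kind
        assert np.array_equal(back.probs, m.probs)
        assert np.array_equal(back.background, m.background)

    def test_shape_follows_column_rule(self, tmp_path, rng):
        spec = BipartiteSpec(4, 8, 1, 1, kind="di")
        recs = random_records(rng, 4, 40)
        pls = random_placements(rng, recs, spec)
        m = to_model(count_sites(recs, pls, spec), background_counts(recs, pls, spec))
        path = tmp_path / "m.tsv"
        export_matrix(m, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2 + 16  # meta + header + 16 symbol rows
        assert len(lines[1].split("\t")) == 2 + (3 + 7)  # symbol + cols + background
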