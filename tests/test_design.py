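"""Optimizer mechanics: initialization, mutation, selection, export."""

import math

import numpy as np
import pytest

from ribodeplete import (
    Alignment,
    InfeasibleDesignError,
    OligoCandidate,
    OptimizerConfig,
    SelectionRules,
    TmProfile,
    antisense_dna,
    export_probes,
    gap_mask,
    initialize_candidates,
    mutate,
    optimize,
    read_probe_export,
    select_next,
    select_probes,
)
from ribodeplete.design import _ColumnBases


def small_cfg(**kw):
    defaults = dict(n_init=30, cycles=5, seed=7)
    defaults.update(kw)
    return OptimizerConfig(**defaults)


class TestInitialize:
    def test_default_population_and_length_range(self, blockish_alignment):
        a, mask, _ = blockish_alignment
        cfg = OptimizerConfig(seed=1)  # 16S profile defaults
        cands = initialize_candidates(a, mask, cfg, np.random.default_rng(1))
        assert len(cands) == 500
        assert all(15 <= c.length <= 24 for c in cands)
        assert all(mask.window_containing(*c.window) is not None for c in cands)

    def test_conserved_alignment_yields_consensus_sequences(self, conserved_alignment):
        a, mask = conserved_alignment
        cands = initialize_candidates(a, mask, small_cfg(), np.random.default_rng(5))
        for c in cands:
            assert c.sense_seq == a.rows[0][c.start:c.start + c.length]

    def test_seed_reproducibility(self, blockish_alignment):
        a, mask, _ = blockish_alignment
        cfg = small_cfg()
        one = initialize_candidates(a, mask, cfg, np.random.default_rng(9))
        two = initialize_candidates(a, mask, cfg, np.random.default_rng(9))
        other = initialize_candidates(a, mask, cfg, np.random.default_rng(10))
        assert all(x.start == y.start and np.array_equal(x.codes, y.codes)
                   for x, y in zip(one, two))
        assert any(x.start != y.start or not np.array_equal(x.codes, y.codes)
                   for x, y in zip(one, other))

    def test_infeasible_alignment_reports_widest_run(self):
        a = Alignment(["s1", "s2"], ["ACGUA-CGUA", "ACGUAACGUA"])
        with pytest.raises(InfeasibleDesignError, match="widest"):
            initialize_candidates(a, gap_mask(a), OptimizerConfig(seed=0),
                                  np.random.default_rng(0))

    def test_matches_some_species_at_every_position(self, blockish_alignment):
        a, mask, _ = blockish_alignment
        cands = initialize_candidates(a, mask, small_cfg(), np.random.default_rng(2))
        for c in cands:
            window_codes = a.codes[:, c.start:c.start + c.length]
            assert np.all((window_codes == c.codes[None, :]).any(axis=0))


class TestMutate:
    def classify(self, parent, child):
        if child.length < parent.length:
            return "shrink"
        if child.length > parent.length:
            return "extend"
        if child.start != parent.start:
            return "move"
        return "swap_or_copy"

    def test_operator_contracts(self, blockish_alignment, rng):
        a, mask, _ = blockish_alignment
        cfg = small_cfg()
        cands = initialize_candidates(a, mask, cfg, rng)
        colbases = _ColumnBases(a, mask)
        seen = set()
        for parent in cands * 10:
            child = mutate(parent, a, mask, cfg, rng, colbases)
            kind = self.classify(parent, child)
            seen.add(kind)
            lo, hi = cfg.len_bounds
            assert lo <= child.length <= hi
            assert mask.window_containing(*child.window) is not None
            window_codes = a.codes[:, child.start:child.start + child.length]
            assert np.all((window_codes == child.codes[None, :]).any(axis=0))
            ps, pe = parent.window
            cs, ce = child.window
            if kind == "shrink":
                assert abs(parent.length - child.length) <= cfg.step_max
                # shared columns keep their bases
                lo_c, hi_c = max(ps, cs), min(pe, ce)
                assert np.array_equal(
                    child.codes[lo_c - cs:hi_c - cs], parent.codes[lo_c - ps:hi_c - ps]
                )
            if kind == "move":
                assert 1 <= abs(cs - ps) <= cfg.step_max
                lo_c, hi_c = max(ps, cs), min(pe, ce)
                assert np.array_equal(
                    child.codes[lo_c - cs:hi_c - cs], parent.codes[lo_c - ps:hi_c - ps]
                )
            if kind == "swap_or_copy" and not np.array_equal(child.codes, parent.codes):
                diff = np.flatnonzero(child.codes != parent.codes)
                assert diff.size == 1
                col = cs + diff[0]
                assert child.codes[diff[0]] in a.codes[:, col]
        assert {"shrink", "extend", "move", "swap_or_copy"} <= seen

    def test_swap_impossible_on_single_species(self, rng):
        a = Alignment(["only"], ["ACGUACGUACGUACGUACGUACGU"])
        mask = gap_mask(a)
        cfg = small_cfg()
        parent = initialize_candidates(a, mask, cfg, rng)[0]
        for _ in range(200):
            child = mutate(parent, a, mask, cfg, rng)
            # any same-window result must be a faithful copy (no swap possible)
            if child.start == parent.start and child.length == parent.length:
                assert np.array_equal(child.codes, parent.codes)


class TestSelectNext:
    def cand(self, min_tm, start=0, length=20):
        c = OligoCandidate(id=0, start=start, codes=np.zeros(length, dtype=np.int8))
        c.min_tm = min_tm
        c.scored = True
        return c

    def test_single_defined_mutant_always_wins(self, rng):
        cfg = OptimizerConfig(seed=0)
        parent = self.cand(math.nan)
        mutants = [self.cand(math.nan) for _ in range(24)] + [self.cand(55.0)]
        for _ in range(50):
            chosen = select_next(parent, mutants, cfg, rng, engine=None)
            assert chosen.min_tm == 55.0

    def test_all_undefined_returns_parent(self, rng):
        cfg = OptimizerConfig(seed=0)
        parent = self.cand(math.nan)
        mutants = [self.cand(math.nan) for _ in range(25)]
        assert select_next(parent, mutants, cfg, rng, engine=None) is parent

    def test_normal_density_pick_ratio(self, rng):
        """Pick frequency at 58.5 vs 62.5 °C follows the e^-2 density ratio."""
        cfg = OptimizerConfig(seed=0)  # target 62.5, sigma 2
        on_target = self.cand(62.5)
        off_target = self.cand(58.5)
        n = 100_000
        picks_off = sum(
            select_next(on_target, [off_target], cfg, rng, engine=None) is off_target
            for _ in range(n)
        )
        p_theory = math.exp(-2.0) / (1.0 + math.exp(-2.0))
        se = math.sqrt(p_theory * (1 - p_theory) / n)
        assert abs(picks_off / n - p_theory) < 3 * se


class TestOptimize:
    def test_zero_cycles_is_identity(self, blockish_alignment):
        a, mask, _ = blockish_alignment
        cfg = small_cfg(cycles=0)
        cands, traj = optimize(a, mask, cfg)
        init = initialize_candidates(a, mask, cfg, np.random.default_rng(cfg.seed))
        assert traj.cycles == []
        assert [c.start for c in cands] == [c.start for c in init]
        assert all(np.array_equal(x.codes, y.codes) for x, y in zip(cands, init))

    def test_feasibility_and_reproducibility(self, blockish_alignment):
        a, mask, _ = blockish_alignment
        cfg = small_cfg()
        cands, traj = optimize(a, mask, cfg, snapshot_cycles=(0, 3, 5))
        for cycle, snap in traj.snapshots.items():
            assert len(snap) == cfg.n_init
            for start, length, _ in snap:
                assert mask.window_containing(start, start + length) is not None
        again, _ = optimize(a, mask, cfg)
        assert all(np.array_equal(x.codes, y.codes) and x.start == y.start
                   for x, y in zip(cands, again))

    def test_species_subset_equal_to_full_set_is_invariant(self, blockish_alignment):
        a, mask, _ = blockish_alignment
        cfg = small_cfg(cycles=3)
        full, _ = optimize(a, mask, cfg)
        sub, _ = optimize(a.subset(a.species_ids), None, cfg)
        assert all(x.start == y.start and np.array_equal(x.codes, y.codes)
                   for x, y in zip(full, sub))

    def test_candidates_converge_into_conserved_blocks(self):
        """Occupancy of the truth blocks increases over optimization.

        Spacers are gap-free but highly divergent, so initial candidates are
        spread across the whole alignment and must migrate into the blocks.
        """
        from ribodeplete import AlignmentRecipe, make_alignment
        recipe = AlignmentRecipe.evenly_spaced(gap_probability=0.0, seed=5)
        a, blocks = make_alignment(recipe)
        mask = gap_mask(a)
        in_block = np.zeros(a.length, dtype=bool)
        for s, l in blocks:
            in_block[s:s + l] = True

        def block_fraction(snap):
            inside = sum(in_block[s:s + l].all() for s, l, _ in snap)
            return inside / len(snap)

        cfg = small_cfg(n_init=60, cycles=15, seed=13)
        _, traj = optimize(a, mask, cfg, snapshot_cycles=(0, 15))
        assert block_fraction(traj.snapshots[15]) > block_fraction(traj.snapshots[0])


def make_profiled(start, length, min_tm, species=4):
    c = OligoCandidate(id=start, start=start,
                       codes=np.zeros(length, dtype=np.int8))
    c.min_tm = min_tm
    c.scored = True
    c.profile = TmProfile.from_tms(
        [f"s{i}" for i in range(species)], np.full(species, float(min_tm))
    )
    return c


class TestSelectProbes:
    def test_shorter_of_two_overlapping_equals_wins(self):
        cfg = OptimizerConfig(seed=0)
        c28 = make_profiled(10, 28, 62.0)
        c34 = make_profiled(12, 34, 62.0)
        ps = select_probes([c34, c28], cfg, SelectionRules(n_target=5))
        assert len(ps.probes) == 1
        assert ps.probes[0].end - ps.probes[0].start + 1 == 28

    def test_minority_above_floor_excluded(self):
        cfg = OptimizerConfig(seed=0)
        c = OligoCandidate(id=0, start=0, codes=np.zeros(20, dtype=np.int8))
        tms = np.array([55.0, 60.0, 58.0] + [45.0] * 5)  # 3 of 8 above 50
        c.profile = TmProfile.from_tms([f"s{i}" for i in range(8)], tms)
        c.min_tm, c.scored = 45.0, True
        ps = select_probes([c], cfg, SelectionRules(n_target=5))
        assert ps.probes == []
        assert "warning" in ps.provenance

    def test_disjoint_candidates_all_returned(self):
        cfg = OptimizerConfig(seed=0)
        cands = [make_profiled(i * 50, 20, 60.0 + i) for i in range(4)]
        ps = select_probes(cands, cfg, SelectionRules(n_target=10))
        assert len(ps.probes) == 4
        starts = [p.start for p in ps.probes]
        assert starts == sorted(starts)

    def test_min_spacing_enforced(self):
        cfg = OptimizerConfig(seed=0)
        cands = [make_profiled(0, 20, 62.5), make_profiled(25, 20, 62.0)]
        tight = select_probes(cands, cfg, SelectionRules(n_target=5, min_spacing=10))
        loose = select_probes(cands, cfg, SelectionRules(n_target=5, min_spacing=0))
        assert len(tight.probes) == 1 and len(loose.probes) == 2

    def test_undefined_profiles_excluded(self):
        cfg = OptimizerConfig(seed=0)
        bad = OligoCandidate(id=0, start=0, codes=np.zeros(20, dtype=np.int8))
        bad.profile = TmProfile.from_tms(["s0", "s1"], np.array([60.0, math.nan]))
        ps = select_probes([bad, make_profiled(40, 20, 61.0)], cfg,
                           SelectionRules(n_target=5))
        assert len(ps.probes) == 1 and ps.probes[0].start == 41


class TestExport:
    def test_antisense_is_reverse_complement_dna(self):
        assert antisense_dna("AAGG") == "CCTT"
        assert antisense_dna("ACGUACGU") == "ACGTACGT"

    def test_roundtrip_and_biotin_annotation(self, tmp_path, conserved_alignment):
        a, mask = conserved_alignment
        cfg = small_cfg(cycles=3)
        cands, _ = optimize(a, mask, cfg)
        ps = select_probes(cands, cfg, SelectionRules(n_target=4))
        assert ps.probes, "expected at least one selectable probe"
        tsv = tmp_path / "probes.tsv"
        fasta = tmp_path / "probes.fasta"
        export_probes(ps, tsv, fasta)
        back = read_probe_export(tsv)
        for p, q in zip(ps.probes, back.probes):
            assert (p.id, p.target, p.start, p.end, p.sense_seq,
                    p.antisense_dna, p.modification) == \
                   (q.id, q.target, q.start, q.end, q.sense_seq,
                    q.antisense_dna, q.modification)
            assert q.modification == "5Biotin"
            assert p.min_tm == pytest.approx(q.min_tm, abs=5e-3)
            assert p.antisense_dna == antisense_dna(p.sense_seq)
        assert all(" 5Biotin" in line for line in fasta.read_text().splitlines()
                   if line.startswith(">"))

    def test_same_seed_byte_identical_exports(self, tmp_path, conserved_alignment):
        a, mask = conserved_alignment
        cfg = small_cfg(cycles=3)
        outs = []
        for name in ("one.tsv", "two.tsv"):
            cands, _ = optimize(a, mask, cfg)
            ps = select_probes(cands, cfg, SelectionRules(n_target=4))
            export_probes(ps, tmp_path / name)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]
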