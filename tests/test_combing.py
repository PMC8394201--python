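import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import replifire as rf
from replifire.combing import reshape_dataset


def annotate(bits):
    return rf.extract_tracks(np.array(bits, dtype=np.uint8))


def eyes_of(ann):
    return list(zip(ann.eye_start.tolist(), ann.eye_end.tolist()))


def oracle_all_merge_orders(eyes, min_gap=1.0, min_eye=1.0):
    """Exhaustively apply single gap-merges in every possible order and
    return the set of resulting reshaped eye lists (after eye filtering)."""
    results = set()

    def rec(ee):
        mergeable = [
            i for i in range(len(ee) - 1) if ee[i + 1][0] - ee[i][1] <= min_gap
        ]
        if not mergeable:
            final = tuple((s, e) for s, e in ee if e - s > min_eye)
            results.add(final)
            return
        for i in mergeable:
            rec(ee[:i] + [(ee[i][0], ee[i + 1][1])] + ee[i + 2:])

    rec(list(eyes))
    return results


class TestReshape:
    def test_small_gap_merges_flanking_eyes(self):
        # 2 kb eye / 1 kb gap / 2 kb eye -> one 5 kb eye
        ann = annotate([1, 1, 0, 1, 1])
        out = rf.reshape_tracks(ann)
        assert eyes_of(out) == [(0.0, 5.0)]

    def test_isolated_small_eye_removed(self):
        ann = annotate([0, 0, 1, 0, 0, 0])
        out = rf.reshape_tracks(ann)
        assert out.n_eyes == 0

    def test_significant_gap_preserved(self):
        ann = annotate([1, 1, 0, 0, 1, 1])
        out = rf.reshape_tracks(ann)
        assert eyes_of(out) == [(0.0, 2.0), (4.0, 6.0)]

    def test_exhaustive_merge_order_oracle_small_strings(self):
        """All binary strings up to length 12: every merge order reaches the
        same fixed point, which the implementation reproduces; the
        implementation is idempotent."""
        for n in range(1, 13):
            for bits in itertools.product((0, 1), repeat=n):
                ann = annotate(bits)
                out = rf.reshape_tracks(ann)
                expected = oracle_all_merge_orders(eyes_of(ann))
                assert len(expected) == 1, f"non-confluent for {bits}"
                assert tuple(eyes_of(out)) == next(iter(expected)), bits
                again = rf.reshape_tracks(out)
                assert eyes_of(again) == eyes_of(out), bits

    @given(st.lists(st.integers(0, 1), min_size=13, max_size=20))
    @settings(deadline=None, max_examples=300)
    def test_merge_order_oracle_longer_strings(self, bits):
        ann = annotate(bits)
        out = rf.reshape_tracks(ann)
        expected = oracle_all_merge_orders(eyes_of(ann))
        assert len(expected) == 1
        assert tuple(eyes_of(out)) == next(iter(expected))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=200)
    def test_reshape_monotonicity(self, bits):
        """Reshaping never decreases mean eye length nor increases the eye
        count, and is idempotent."""
        ann = annotate(bits)
        out = rf.reshape_tracks(ann)
        assert out.n_eyes <= ann.n_eyes
        if out.n_eyes and ann.n_eyes:
            assert out.eye_lengths.mean() >= ann.eye_lengths.mean() - 1e-12
        again = rf.reshape_tracks(out)
        assert eyes_of(again) == eyes_of(out)

    def test_dataset_reshape_matches_per_molecule(self, rng):
        mols = []
        for _ in range(30):
            bits = (rng.random(rng.integers(5, 40)) < 0.4).astype(int)
            mols.append((len(bits), eyes_of(annotate(bits))))
        ds = rf.CombingDataset.from_molecules(mols)
        out = reshape_dataset(ds)
        for i in range(ds.n_molecules):
            single = rf.reshape_tracks(ds.molecule(i))
            assert eyes_of(out.molecule(i)) == eyes_of(single)


class TestClassifyNewFirings:
    @pytest.mark.parametrize(
        "eyes,expected",
        [
            ([(2.0, 4.0)], 1),  # 2 kb eye -> new firing
            ([(2.0, 6.0)], 0),  # 4 kb eye -> too old
            ([(2.0, 5.0)], 1),  # 3 kb boundary included
            ([(2.0, 3.0)], 0),  # 1 kb eye: below detection, not scored
        ],
    )
    def test_window(self, eyes, expected):
        ds = rf.CombingDataset.from_molecules([(10.0, eyes)])
        assert rf.classify_new_firings(ds).tolist() == [expected]


class TestShredding:
    def test_point_mass_whole_genome(self):
        blocks = np.zeros(1000, dtype=np.uint8)
        rng = np.random.default_rng(0)
        ds = rf.shred_genome(blocks, rf.LengthModel.point(1000), rng)
        # a molecule as long as the genome fits only when the offset is 0;
        # otherwise both partial stretches are discarded
        assert ds.n_molecules <= 1

    def test_point_mass_tiling(self):
        blocks = np.zeros(100_000, dtype=np.uint8)
        rng = np.random.default_rng(1)
        ds = rf.shred_genome(blocks, rf.LengthModel.point(100), rng)
        # both stretches tile fully up to one discarded partial each
        assert ds.n_molecules in (998, 999, 1000)
        assert np.all(ds.lengths == 100)

    def test_global_fraction_matches_genome(self):
        rng = np.random.default_rng(2)
        blocks = (rng.random(200_000) < 0.3).astype(np.uint8)
        ds = rf.shred_genome(blocks, rf.LengthModel.point(100), rng)
        assert ds.global_fraction == pytest.approx(blocks.mean(), abs=0.01)

    def test_lengths_follow_source_distribution(self):
        """Sampled molecule lengths pass a KS test against a fresh sample
        from the same lognormal source."""
        blocks = np.zeros(1_200_000, dtype=np.uint8)
        lm = rf.LengthModel.lognormal(median=100.0, sigma=0.5)
        rng = np.random.default_rng(3)
        ds = rf.shred_genome(blocks, lm, rng)
        reference = np.rint(np.maximum(1, lm(ds.n_molecules, rng)))
        stat = stats.ks_2samp(ds.lengths, reference)
        assert stat.pvalue > 0.01

    def test_shredded_fraction_converges_with_genome_size(self):
        """Shredded global fraction approaches the genome fraction as the
        molecule count grows (three genome sizes, shrinking error)."""
        errs = []
        for k, L in enumerate((20_000, 200_000, 2_000_000)):
            rng = np.random.default_rng(7)
            blocks = np.zeros(L, dtype=np.uint8)
            idx = rng.choice(L, size=L // 4, replace=False)
            blocks[idx] = 1
            err = []
            for seed in range(5):
                ds = rf.shred_genome(
                    blocks, rf.LengthModel.point(97), np.random.default_rng(seed)
                )
                err.append(abs(ds.global_fraction - 0.25))
            errs.append(np.mean(err))
        assert errs[2] < errs[0]


@pytest.fixture(scope="module")
def trajectory():
    p = rf.ModelParameters(N0=40, J=8, Pout=3e-3, variant="MM1")
    return rf.run_simulation(
        p, 50_000, 11, snapshot_f=[0.0, 0.15, 1.0], snapshot_window=0.05
    )


class TestMatching:

    def test_target_zero_is_round_zero(self, trajectory, rng):
        ds = rf.match_global_fraction(
            trajectory, rf.LengthModel.point(100), 0.0, rng=rng
        )
        assert ds.meta["source_round"] == 0
        assert ds.global_fraction == 0.0

    def test_target_one_is_final_round(self, trajectory, rng):
        ds = rf.match_global_fraction(
            trajectory, rf.LengthModel.point(100), 1.0, rng=rng
        )
        assert ds.meta["source_round"] == int(trajectory.rounds[-1])
        assert ds.global_fraction == 1.0

    def test_matched_fraction_within_tolerance(self, trajectory, rng):
        ds = rf.match_global_fraction(
            trajectory, rf.LengthModel.point(100), 0.15, tol=0.02, rng=rng,
            reshape=False,
        )
        assert abs(ds.global_fraction - 0.15) <= 0.02

    def test_unreachable_target_raises(self, trajectory, rng):
        with pytest.raises(rf.MatchError):
            rf.match_global_fraction(
                trajectory, rf.LengthModel.point(100), 0.5, tol=1e-6, rng=rng
            )


class TestPerMoleculeCurves:
    def test_unreplicated_molecule(self):
        ds = rf.CombingDataset.from_molecules([(100.0, [])])
        cur = rf.per_molecule_curves(ds)
        assert cur.frac_hist[0] == 1.0
        assert cur.fork_density[0] == 0.0
        assert cur.firing_rate[0] == 0.0

    def test_single_new_firing_formula(self):
        # one interior 2 kb eye on a 100 kb molecule: f = 0.02,
        # I = 1 / (0.98 * 100 * 3)
        ds = rf.CombingDataset.from_molecules([(100.0, [(50.0, 52.0)])])
        cur = rf.per_molecule_curves(ds)
        expected = 1.0 / (0.98 * 100.0 * 3.0)
        assert np.nansum(cur.firing_rate) == pytest.approx(expected)
        assert np.nansum(cur.fork_density) == pytest.approx(2 / 100.0)

    def test_end_touching_eye_counts_one_fork(self):
        ds = rf.CombingDataset.from_molecules([(50.0, [(0.0, 10.0)])])
        cur = rf.per_molecule_curves(ds)
        assert np.nansum(cur.fork_density) == pytest.approx(1 / 50.0)

    def test_binning_matches_brute_force_group_by(self, rng):
        """Bin averages equal a hand group-by on a 20-molecule toy set."""
        mols = []
        for _ in range(20):
            n = int(rng.integers(20, 60))
            bits = (rng.random(n) < rng.uniform(0.05, 0.6)).astype(int)
            ann = annotate(bits)
            mols.append((float(n), eyes_of(ann)))
        ds = reshape_dataset(rf.CombingDataset.from_molecules(mols))
        cur = rf.per_molecule_curves(ds, n_f_bins=10)
        fmol = ds.molecule_fractions()
        n_new = rf.classify_new_firings(ds)
        edges = np.linspace(0, 1, 11)
        for b in range(10):
            lo, hi = edges[b], edges[b + 1]
            sel = (fmol >= lo) & (fmol < hi) if b < 9 else (fmol >= lo)
            sel &= fmol < 1.0
            if not sel.any():
                continue
            vals = n_new[sel] / ((1 - fmol[sel]) * ds.lengths[sel] * 3.0)
            assert cur.firing_rate[b] == pytest.approx(vals.mean())

    def test_tsv_round_trip(self, tmp_path, rng):
        mols = [
            (120.0, [(10.0, 14.5), (30.0, 33.0)]),
            (80.0, []),
            (55.5, [(0.0, 55.5)]),
        ]
        ds = rf.CombingDataset.from_molecules(mols)
        path = tmp_path / "molecules.tsv"
        ds.to_tsv(path)
        back = rf.CombingDataset.from_tsv(path)
        assert np.allclose(back.lengths, ds.lengths)
        assert np.allclose(back.eye_start, ds.eye_start)
        assert np.allclose(back.eye_end, ds.eye_end)
        assert back.global_fraction == pytest.approx(ds.global_fraction)


def test_end_truncation_bias(rng):
    """Mean observed eye-to-eye distance on finite molecules does not
    exceed the genome-wide mean inter-initiation distance (finite-length
    detection bias: long distances fall off molecule ends)."""
    p = rf.ModelParameters(N0=60, J=10, Pout=2e-3, variant="MM1")
    traj = rf.run_simulation(p, 200_000, 13, f_target=0.35, snapshot_f=[0.3])
    blocks = traj.snapshots[max(traj.snapshots)]
    genome_ann = rf.extract_tracks(blocks)
    genome_mean = genome_ann.eted.mean()
    ds = rf.shred_genome(blocks, rf.LengthModel.point(75), rng)
    cur_eted = []
    for i in range(ds.n_molecules):
        cur_eted.extend(ds.molecule(i).eted.tolist())
    assert np.mean(cur_eted) <= genome_mean
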