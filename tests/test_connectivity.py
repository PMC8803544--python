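"""Connectivity estimation, network blocks and paired inference."""

import numpy as np
import pytest
from scipy import stats

import respkit as rk


def make_ts(data, networks=None, tr_s=0.8):
    p = data.shape[1]
    ids = [f"p{i}" for i in range(p)]
    if networks is None:
        networks = {i: "n" for i in ids}
    else:
        networks = {f"p{i}": n for i, n in enumerate(networks)}
    return rk.ParcelTimeseries(data=data, parcel_ids=ids, network_of=networks, tr_s=tr_s)


def full_mask(t, thr=0.2):
    return rk.FrameMask(keep=np.ones(t, bool), threshold_mm=thr)


def pearson_loop_oracle(data):
    t, p = data.shape
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            x, y = data[:, i], data[:, j]
            xc, yc = x - x.mean(), y - y.mean()
            r[i, j] = r[j, i] = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    return r


class TestBandpassInterp:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(3000)
        data = np.sin(2 * np.pi * 0.03 * t * 0.8)[:, None] * np.ones((1, 3))
        ts = make_ts(data)
        out = rk.bandpass_interp(ts, full_mask(3000))
        mid = slice(500, -500)
        ratio = np.ptp(out.data[mid, 0]) / np.ptp(data[mid, 0])
        assert ratio == pytest.approx(1.0, abs=0.10)

    def test_out_of_band_attenuated_20db(self):
        t = np.arange(3000)
        x = np.sin(2 * np.pi * 0.4 * t * 0.8)
        ts = make_ts(x[:, None] * np.ones((1, 2)))
        out = rk.bandpass_interp(ts, full_mask(3000))
        assert np.sqrt(np.mean(out.data[:, 0] ** 2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_constant_signal_removed(self):
        ts = make_ts(np.full((200, 2), 7.0))
        out = rk.bandpass_interp(ts, full_mask(200))
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_censored_frames_interpolated_not_zeroed(self):
        rng = np.random.default_rng(0)
        slow = np.sin(2 * np.pi * 0.02 * np.arange(500) * 0.8)
        data = (slow + 0.01 * rng.standard_normal(500))[:, None]
        keep = np.ones(500, bool)
        keep[100:110] = False
        ts = make_ts(data)
        gap = rk.bandpass_interp(ts, rk.FrameMask(keep=keep, threshold_mm=0.2))
        ref = rk.bandpass_interp(ts, full_mask(500))
        # a short gap in a slow signal reconstructs close to the gap-free result
        assert np.max(np.abs(gap.data - ref.data)) < 0.05 * np.ptp(ref.data)

    def test_too_few_kept_frames_rejected(self):
        ts = make_ts(np.random.default_rng(0).normal(size=(50, 2)))
        keep = np.zeros(50, bool)
        keep[3] = True
        with pytest.raises(ValueError, match="2 retained"):
            rk.bandpass_interp(ts, rk.FrameMask(keep=keep, threshold_mm=0.2))

    def test_band_must_be_below_nyquist(self):
        ts = make_ts(np.zeros((100, 2)), tr_s=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            rk.bandpass_interp(ts, full_mask(100), lo_hz=0.008, hi_hz=0.09)


class TestFcMatrix:
    def test_identical_signals_r_one(self, rng):
        x = rng.normal(size=30)
        cm = rk.fc_matrix(make_ts(np.column_stack([x, x])), full_mask(30))
        assert cm.r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_opposite_signals_r_minus_one(self, rng):
        x = rng.normal(size=30)
        cm = rk.fc_matrix(make_ts(np.column_stack([x, -x])), full_mask(30))
        assert cm.r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        data = rng.normal(size=(40, 3))
        cm = rk.fc_matrix(make_ts(data), full_mask(40))
        np.testing.assert_allclose(cm.r, pearson_loop_oracle(data), atol=1e-12)

    def test_only_kept_frames_used(self, rng):
        data = rng.normal(size=(60, 3))
        keep = np.zeros(60, bool)
        keep[::3] = True
        cm = rk.fc_matrix(make_ts(data), rk.FrameMask(keep=keep, threshold_mm=0.2))
        np.testing.assert_allclose(cm.r, pearson_loop_oracle(data[keep]), atol=1e-12)
        assert cm.n_frames_used == keep.sum()

    def test_zero_variance_parcel_zeroed_with_warning(self, rng):
        data = rng.normal(size=(30, 3))
        data[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = rk.fc_matrix(make_ts(data), full_mask(30))
        assert np.all(cm.r[1, [0, 2]] == 0)
        assert cm.r[1, 1] == 1.0

    def test_minimum_frame_floor(self, rng):
        data = rng.normal(size=(9, 3))
        with pytest.raises(ValueError, match="at least 10"):
            rk.fc_matrix(make_ts(data), full_mask(9))


class TestNetworkBlocks:
    def test_block_constant_toy_exact(self):
        r = np.full((4, 4), 0.1)
        r[:2, :2] = 0.6
        r[2:, 2:] = 0.6
        np.fill_diagonal(r, 1.0)
        cm = rk.ConnectivityMatrix(
            r=r, n_frames_used=100,
            parcel_ids=["a", "b", "c", "d"],
            network_of={"a": "n1", "b": "n1", "c": "n2", "d": "n2"},
        )
        blocks = rk.network_blocks(cm)
        np.testing.assert_allclose(blocks.blocks, [[0.6, 0.1], [0.1, 0.6]], atol=1e-15)

    def test_matches_pair_enumeration_oracle(self, rng):
        p = 9
        labels = ["x"] * 3 + ["y"] * 4 + ["z"] * 2
        a = rng.uniform(-1, 1, size=(p, p))
        r = (a + a.T) / 2
        np.fill_diagonal(r, 1.0)
        cm = rk.ConnectivityMatrix(
            r=r, n_frames_used=50,
            parcel_ids=[f"p{i}" for i in range(p)],
            network_of={f"p{i}": labels[i] for i in range(p)},
        )
        blocks = rk.network_blocks(cm)
        nets = blocks.network_labels
        for ai, na in enumerate(nets):
            for bi, nb in enumerate(nets):
                vals = [
                    r[i, j]
                    for i in range(p) for j in range(p)
                    if labels[i] == na and labels[j] == nb and (
                        (na != nb) or i < j
                    )
                ]
                np.testing.assert_allclose(blocks.blocks[ai, bi], np.mean(vals), atol=1e-12)

    def test_singleton_network_within_cell_missing(self):
        r = np.eye(3)
        cm = rk.ConnectivityMatrix(
            r=r, n_frames_used=50,
            parcel_ids=["a", "b", "c"],
            network_of={"a": "n1", "b": "n1", "c": "solo"},
        )
        with pytest.warns(UserWarning, match="singleton"):
            blocks = rk.network_blocks(cm)
        i = blocks.network_labels.index("solo")
        assert np.isnan(blocks.blocks[i, i])


def _random_cm(rng, p=6, labels=None):
    a = rng.normal(size=(60, p))
    return rk.fc_matrix(
        make_ts(a, networks=labels or ["n1"] * (p // 2) + ["n2"] * (p - p // 2)),
        full_mask(60),
    )


class TestPairedTTest:
    def test_identical_lists_give_zero_t(self, rng):
        mats = [_random_cm(rng) for _ in range(4)]
        res = rk.paired_ttest(mats, mats)
        off = ~np.eye(len(mats[0].parcel_ids), dtype=bool)
        assert np.all(np.nan_to_num(res.t[off]) == 0)
        assert res.df == 3

    def test_unequal_lists_rejected(self, rng):
        mats = [_random_cm(rng) for _ in range(4)]
        with pytest.raises(ValueError, match="equal length"):
            rk.paired_ttest(mats, mats[:3])

    def test_matches_closed_form_on_average(self):
        # paired t of a constant z-shift d with noise sd s over n subjects
        # concentrates around d / (s / sqrt(n))
        d, s, n = 0.15, 0.10, 12
        expected = d / (s / np.sqrt(n))
        tvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            mats_a, mats_b = [], []
            for _ in range(n):
                z0 = rng.uniform(0.1, 0.5)
                za = z0 + d + rng.normal(0, s)  # all noise on the difference
                zb = z0
                ra, rb = np.tanh(za), np.tanh(zb)
                base = np.eye(2)
                a, b = base.copy(), base.copy()
                a[0, 1] = a[1, 0] = ra
                b[0, 1] = b[1, 0] = rb
                ids, nets = ["p0", "p1"], {"p0": "n", "p1": "n"}
                mats_a.append(rk.ConnectivityMatrix(a, 50, ids, nets))
                mats_b.append(rk.ConnectivityMatrix(b, 50, ids, nets))
            tvals.append(rk.paired_ttest(mats_a, mats_b).t[0, 1])
        # the noncentral-t mean exceeds the plug-in value by a few percent
        # at df=11; 10% tolerance covers that plus Monte-Carlo spread
        assert np.mean(tvals) == pytest.approx(expected, rel=0.10)

    def test_network_block_level_shapes(self, rng):
        mats_a = [_random_cm(rng) for _ in range(5)]
        mats_b = [_random_cm(rng) for _ in range(5)]
        res = rk.paired_ttest(mats_a, mats_b, level="network_block")
        assert res.t.shape == (2, 2)
        assert res.labels == ["n1", "n2"]

    def test_fdr_adjusted_p_not_smaller_than_raw(self, rng):
        mats_a = [_random_cm(rng) for _ in range(5)]
        mats_b = [_random_cm(rng) for _ in range(5)]
        res = rk.paired_ttest(mats_a, mats_b, fdr=True)
        iu = np.triu_indices(len(res.labels), k=1)
        assert np.all(res.p_fdr[iu] >= res.p[iu] - 1e-12)
        np.testing.assert_allclose(res.p_fdr, res.p_fdr.T, equal_nan=True)

    def test_fisher_z_round_trip(self):
        r = np.array([-0.9, 0.0, 0.35, 0.99])
        np.testing.assert_allclose(rk.inverse_fisher_z(rk.fisher_z(r)), r, atol=1e-12)


class TestArtifactInjection:
    def test_adding_corrupted_frames_never_helps(self):
        """Appending motion-corrupted frames to the kept set does not
        improve agreement with the generator's target covariance."""
        bp = rk.BoldSimParams(corruption_gain=3.0)
        truth_r = bp.target_correlation()
        iu = np.triu_indices(bp.p_parcels, k=1)
        worse = 0
        for seed in range(10):
            mp = rk.MotionSimParams(spike_rate_per_min=6.0)
            motion, truth = rk.gen_motion(mp, seed=seed)
            bold = rk.gen_bold(bp, truth, seed=seed)
            fd = rk.compute_fd(rk.apply_notch(motion, rk.infant_toddler_notch()))
            clean = rk.censor(fd)
            dirty = rk.FrameMask(keep=np.ones(fd.n_frames, bool), threshold_mm=9.9)
            r_clean = rk.fc_matrix(bold, clean).r
            r_dirty = rk.fc_matrix(bold, dirty).r
            agree_clean = np.corrcoef(r_clean[iu], truth_r[iu])[0, 1]
            agree_dirty = np.corrcoef(r_dirty[iu], truth_r[iu])[0, 1]
            worse += agree_dirty <= agree_clean + 1e-6
        assert worse >= 9
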