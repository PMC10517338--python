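"""Effect-score adapters vs independent nested-loop oracles."""

import math

import numpy as np
import pytest

from utrcensus.effect_scoring import (
    PredictionTensor,
    build_six_channel_track,
    orf_effect,
    phylop_annotate,
    stability_effect,
    transcription_effect,
)
from utrcensus.io_formats import ConservationTrack, VariantRecord


def tensor(values, center=None):
    values = np.asarray(values, dtype=float)
    if center is None:
        center = values.shape[1] // 2
    return PredictionTensor(values=values, center_window=center)


# ---------------------------------------------------------------------------
# transcription effect
# ---------------------------------------------------------------------------


def oracle_transcription(ref, alt, cage_tracks, n_windows):
    """Nested-loop re-implementation of the window/track aggregation."""

    def score(t):
        half = (n_windows - 1) // 2
        per_track = []
        for track in cage_tracks:
            total = 0.0
            for w in range(t.center_window - half, t.center_window + half + 1):
                fwd = t.values[0][w][track]
                rev = t.values[1][w][track]
                total += (fwd + rev) / 2.0
            per_track.append(math.log2(1.0 + total))
        return sum(per_track) / len(per_track)

    return score(alt) - score(ref)


def test_transcription_identity():
    t = tensor(np.ones((2, 5, 3)))
    assert transcription_effect(t, t, [0, 1, 2]).raw == 0.0


def test_transcription_single_track_known_value():
    # one track, fwd == rev; ref window-sum 1, alt window-sum 3
    ref = np.zeros((2, 5, 1))
    ref[:, 2, 0] = 1.0  # both strands 1 at center -> strand-avg sum = 1
    alt = np.zeros((2, 5, 1))
    alt[:, 1, 0] = 1.0
    alt[:, 2, 0] = 2.0  # strand-avg window sums: 1 + 2 = 3
    effect = transcription_effect(tensor(ref), tensor(alt), [0])
    assert effect.raw == pytest.approx(math.log2(4) - math.log2(2), abs=1e-12)
    assert effect.raw == pytest.approx(1.0, abs=1e-12)


def test_transcription_mean_over_tracks():
    # track 0 contributes raw 1.0 (sums 1 -> 3), track 1 contributes 0.0
    ref = np.zeros((2, 5, 2))
    alt = np.zeros((2, 5, 2))
    ref[:, 2, 0], alt[:, 2, 0] = 1.0, 3.0
    ref[:, 2, 1], alt[:, 2, 1] = 2.0, 2.0
    effect = transcription_effect(tensor(ref), tensor(alt), [0, 1])
    assert effect.raw == pytest.approx(0.5, abs=1e-12)


def test_transcription_oracle_random_tensors():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n_windows = int(rng.integers(5, 10))
        n_tracks = int(rng.integers(1, 5))
        center = int(rng.integers(2, n_windows - 2)) if n_windows > 5 else 2
        ref = tensor(rng.gamma(1.0, 2.0, size=(2, n_windows, n_tracks)), center)
        alt = tensor(rng.gamma(1.0, 2.0, size=(2, n_windows, n_tracks)), center)
        k = int(rng.integers(1, n_tracks + 1))
        cage = list(rng.choice(n_tracks, size=k, replace=False))
        got = transcription_effect(ref, alt, cage).raw
        expected = oracle_transcription(ref, alt, cage, 5)
        assert got == pytest.approx(expected, abs=1e-12)


def test_transcription_invariances():
    rng = np.random.default_rng(7)
    ref = tensor(rng.gamma(1.0, 2.0, size=(2, 9, 3)), center=4)
    alt = tensor(rng.gamma(1.0, 2.0, size=(2, 9, 3)), center=4)
    base = transcription_effect(ref, alt, [0, 2]).raw
    # permuting the track order leaves the mean unchanged
    assert transcription_effect(ref, alt, [2, 0]).raw == pytest.approx(base, abs=1e-12)
    # windows outside the selected five are irrelevant
    ref2 = tensor(ref.values.copy(), center=4)
    alt2 = tensor(alt.values.copy(), center=4)
    ref2.values[:, 0, :] = 99.0
    alt2.values[:, 8, :] = -1.0
    assert transcription_effect(ref2, alt2, [0, 2]).raw == pytest.approx(base, abs=1e-12)
    # antisymmetry under ref/alt swap
    assert transcription_effect(alt, ref, [0, 2]).raw == pytest.approx(-base, abs=1e-12)


def test_transcription_input_errors():
    t = tensor(np.ones((2, 3, 2)), center=1)
    with pytest.raises(ValueError, match="windows"):
        transcription_effect(t, t, [0])
    t5 = tensor(np.ones((2, 5, 2)))
    with pytest.raises(ValueError, match="cage_tracks"):
        transcription_effect(t5, t5, [])
    with pytest.raises(ValueError, match="odd"):
        transcription_effect(t5, t5, [0], n_windows=4)


# ---------------------------------------------------------------------------
# stability effect
# ---------------------------------------------------------------------------


def test_stability_examples():
    assert stability_effect([1.0, 2.0], [1.0, 2.0]).raw == 0.0
    assert stability_effect([0.0, 0.0], [1.0, 3.0]).raw == 2.0
    assert stability_effect([0.7], [0.3]).raw == pytest.approx(-0.4)


def test_stability_exact_antisymmetry():
    rng = np.random.default_rng(3)
    for _ in range(100):
        k = int(rng.integers(1, 51))
        ref = list(rng.normal(size=k))
        alt = list(rng.normal(size=k))
        assert stability_effect(ref, alt).raw + stability_effect(alt, ref).raw == 0.0
        # matches the plain arithmetic oracle
        expected = sum(alt) / k - sum(ref) / k
        assert stability_effect(ref, alt).raw == pytest.approx(expected, abs=1e-12)


def test_stability_unequal_lengths_rejected():
    with pytest.raises(ValueError, match="length"):
        stability_effect([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# ORF effect
# ---------------------------------------------------------------------------


def test_orf_effect_scales():
    assert orf_effect(2.0, 2.0).raw == 0.0
    assert orf_effect(2.0, 1.0).raw == pytest.approx(-1.0, abs=1e-12)
    assert orf_effect(2.0, 1.0, scale="ratio").raw == pytest.approx(0.5, abs=1e-12)


def test_orf_effect_swap_symmetry():
    # log2 scale: swap negates; ratio scale: swap inverts
    assert orf_effect(3.0, 7.0).raw == pytest.approx(-orf_effect(7.0, 3.0).raw, abs=1e-12)
    assert orf_effect(3.0, 7.0, scale="ratio").raw == pytest.approx(
        1.0 / orf_effect(7.0, 3.0, scale="ratio").raw, abs=1e-12
    )


def test_orf_effect_rejects_nonpositive():
    with pytest.raises(ValueError, match="positive"):
        orf_effect(0.0, 1.0)
    with pytest.raises(ValueError, match="positive"):
        orf_effect(1.0, -2.0)


def test_abs_property():
    for raw_source in (orf_effect(2.0, 1.0), stability_effect([0.0], [-3.0])):
        assert raw_source.abs == abs(raw_source.raw) >= 0


# ---------------------------------------------------------------------------
# six-channel track
# ---------------------------------------------------------------------------


def test_six_channel_identity_one_hot():
    track = build_six_channel_track("ACGT")
    assert np.array_equal(track.values[:, :4], np.eye(4))
    assert not track.values[:, 4:].any()


def test_six_channel_frame_marks_codon_starts():
    track = build_six_channel_track("ACGTCA", coding_interval=(1, 6))
    assert list(track.values[:, 4]) == [1, 0, 0, 1, 0, 0]
    # oracle: walk codons for an offset CDS
    track = build_six_channel_track("AACGTCAG", coding_interval=(3, 8))
    expected = [1.0 if (i >= 2 and (i - 2) % 3 == 0) else 0.0 for i in range(8)]
    assert list(track.values[:, 4]) == expected


def test_six_channel_splice_and_n_handling():
    track = build_six_channel_track("ANGT", splice_positions={3})
    assert not track.values[1, :4].any()  # N -> all-zero one-hot
    assert list(track.values[:, 5]) == [0, 0, 1, 0]
    # one-hot channels sum to 1 wherever the base is defined
    defined = [0, 2, 3]
    assert all(track.values[i, :4].sum() == 1.0 for i in defined)


def test_six_channel_rejects_bad_input():
    with pytest.raises(ValueError, match="non-ACGTN"):
        build_six_channel_track("ACXT")
    with pytest.raises(ValueError, match="bounds"):
        build_six_channel_track("ACGT", splice_positions={9})
    with pytest.raises(ValueError, match="bounds"):
        build_six_channel_track("ACGT", coding_interval=(2, 9))


# ---------------------------------------------------------------------------
# conservation annotation
# ---------------------------------------------------------------------------


def _track(scores_by_pos, chrom="1"):
    track = ConservationTrack()
    for pos, score in scores_by_pos.items():
        track.add(chrom, pos, pos, score)
    return track.finalize()


def test_phylop_snv():
    track = _track({100: 2.3})
    ann = phylop_annotate(VariantRecord(chrom="1", pos=100, ref="A", alt="G"), track)
    assert ann.phylop == 2.3


def test_phylop_multibase_max_rule():
    track = _track({100: 0.2, 101: 1.6, 102: -0.4})
    variant = VariantRecord(chrom="1", pos=100, ref="AAA", alt="A")
    assert phylop_annotate(variant, track).phylop == 1.6


def test_phylop_partial_coverage_uses_covered_subset():
    track = _track({100: 0.2, 102: 0.9})  # 101 uncovered
    variant = VariantRecord(chrom="1", pos=100, ref="AAA", alt="A")
    assert phylop_annotate(variant, track).phylop == 0.9


def test_phylop_uncovered_is_absent():
    track = _track({100: 2.3})
    variant = VariantRecord(chrom="1", pos=500, ref="A", alt="G")
    assert phylop_annotate(variant, track).phylop is None


def test_phylop_oracle_random_tracks():
    rng = np.random.default_rng(11)
    for _ in range(200):
        positions = rng.choice(np.arange(1, 60), size=rng.integers(1, 20), replace=False)
        scores = {int(p): float(rng.normal()) for p in positions}
        track = _track(scores)
        pos = int(rng.integers(1, 50))
        length = int(rng.integers(1, 10))
        variant = VariantRecord(chrom="1", pos=pos, ref="A" * length, alt="A")
        covered = [scores[p] for p in range(pos, pos + length) if p in scores]
        expected = max(covered) if covered else None
        assert phylop_annotate(variant, track).phylop == expected
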