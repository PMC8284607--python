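import numpy as np
import pytest

from mutacc.signatures import (
    SignatureCatalog,
    cosine_similarity,
    read_signature_catalog,
    refit_exposures,
    similarity_matrix,
    write_signature_catalog,
)
from mutacc.simulate import make_catalog, pole_like_signature, random_signature
from mutacc.spectrum import CHANNELS_96, Spectrum96


def _block_catalog() -> SignatureCatalog:
    """Four disjoint-support signatures, uniform over 24 channels each."""
    cols = []
    for i in range(4):
        v = np.zeros(96)
        v[i * 24 : (i + 1) * 24] = 1 / 24
        cols.append(v)
    return SignatureCatalog(("B1", "B2", "B3", "B4"), np.stack(cols, axis=1))


class TestCatalogIO:
    def test_roundtrip_bracket_dialect(self, tmp_path):
        cat = make_catalog(n_random=2, seed=1)
        p = tmp_path / "cat.tsv"
        write_signature_catalog(cat, p)
        back = read_signature_catalog(p)
        assert back.names == cat.names
        assert np.allclose(back.matrix, cat.matrix, atol=1e-12)

    def test_type_subtype_dialect(self, tmp_path):
        cat = make_catalog(n_random=2, seed=2)
        p = tmp_path / "cat.tsv"
        with open(p, "w") as fh:
            fh.write("Type\tSubtype\tS1\tS2\n")
            for i, ch in enumerate(CHANNELS_96):
                sub = ch[2:5]
                tri = ch[0] + ch[2] + ch[6]
                fh.write(f"{sub}\t{tri}\t{cat.matrix[i,0]}\t{cat.matrix[i,1]}\n")
        back = read_signature_catalog(p)
        assert back.names == ("S1", "S2")
        assert np.allclose(back.matrix, cat.matrix, atol=1e-12)

    def test_shuffled_rows_canonicalized(self, tmp_path):
        cat = make_catalog(n_random=2, seed=3)
        frame = cat.to_frame()
        frame.insert(0, "Type", frame.index)
        frame = frame.sample(frac=1, random_state=0)
        p = tmp_path / "cat.tsv"
        frame.to_csv(p, sep="\t", index=False)
        back = read_signature_catalog(p)
        assert np.allclose(back.matrix, cat.matrix, atol=1e-12)

    def test_missing_channel_named_in_error(self, tmp_path):
        cat = make_catalog(n_random=1, seed=4)
        frame = cat.to_frame()
        frame.insert(0, "Type", frame.index)
        frame = frame[frame["Type"] != "T[T>G]T"]
        p = tmp_path / "cat.tsv"
        frame.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match=r"T\[T>G\]T"):
            read_signature_catalog(p)

    def test_column_not_summing_to_one_rejected(self, tmp_path):
        cat = make_catalog(n_random=1, seed=5)
        frame = cat.to_frame() * 2.0
        frame.insert(0, "Type", frame.index)
        p = tmp_path / "cat.tsv"
        frame.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="sum"):
            read_signature_catalog(p)


class TestCosine:
    def test_self_similarity_is_one(self):
        v = random_signature(0)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        a = np.zeros(96); a[0] = 1
        b = np.zeros(96); b[1] = 1
        assert cosine_similarity(a, b) == 0.0

    def test_closed_form_value(self):
        a = np.zeros(96); a[:2] = 1
        b = np.zeros(96); b[0] = 1
        assert cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestSimilarityMatrix:
    def test_exact_catalog_column_is_best_hit_and_high(self):
        cat = _block_catalog()
        res = similarity_matrix({"q": cat["B2"]}, cat)
        hit = res.best_hits.iloc[0]
        assert hit.signature == "B2" and hit.similarity == pytest.approx(1.0)
        assert hit.high and not hit.tied

    def test_orthogonal_spectrum_not_flagged(self):
        cols = [np.zeros(96) for _ in range(2)]
        cols[0][:10] = 0.1
        cols[1][10:20] = 0.1
        cat = SignatureCatalog(("S1", "S2"), np.stack(cols, axis=1))
        q = np.zeros(96); q[50] = 1.0
        res = similarity_matrix({"q": q}, cat)
        assert res.best_hits.iloc[0].similarity == 0.0
        assert not res.best_hits.iloc[0].high

    def test_tie_broken_by_catalog_order_and_reported(self):
        cat = _block_catalog()
        q = cat["B1"] + cat["B3"]
        res = similarity_matrix({"q": q}, cat)
        hit = res.best_hits.iloc[0]
        assert hit.signature == "B1" and hit.tied

    def test_scaling_invariance(self):
        cat = make_catalog(n_random=3, seed=6)
        q = random_signature(7)
        a = similarity_matrix({"q": q}, cat).matrix
        b = similarity_matrix({"q": q * 1000}, cat).matrix
        assert np.allclose(a.values, b.values)

    def test_leaf_order_clusters_the_close_pair(self):
        # s1 and s2 nearly parallel, s3 far: average linkage merges (s1, s2)
        # first, so they are adjacent in leaf order.
        s1 = np.zeros(96); s1[:4] = 0.25
        s2 = np.zeros(96); s2[:4] = 0.2; s2[4] = 0.2
        s3 = np.zeros(96); s3[90:] = 1 / 6
        cat = SignatureCatalog(("s1", "s2", "s3"), np.stack([s1, s2, s3], axis=1))
        order = similarity_matrix({"q": s1}, cat).leaf_order
        i, j = order.index("s1"), order.index("s2")
        assert abs(i - j) == 1


class TestRefit:
    def test_pure_column_recovered_exactly(self):
        cat = make_catalog(n_random=4, seed=8)
        exp = refit_exposures(cat["SBS_R2"], cat)
        assert exp.weights["SBS_R2"] == pytest.approx(1.0, abs=1e-9)
        assert exp.residual_cosine == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_two_signature_mixture(self):
        cat = make_catalog(n_random=4, seed=9)
        mix = 0.7 * cat["SBS_R1"] + 0.3 * cat["SBS_R3"]
        exp = refit_exposures(mix, cat)
        assert exp.weights["SBS_R1"] == pytest.approx(0.7, abs=1e-6)
        assert exp.weights["SBS_R3"] == pytest.approx(0.3, abs=1e-6)

    def test_uniform_spectrum_on_symmetric_catalog_splits_evenly(self):
        cat = _block_catalog()
        exp = refit_exposures(np.full(96, 1 / 96), cat)
        for name in cat.names:
            assert exp.weights[name] == pytest.approx(0.25, abs=1e-9)

    def test_min_weight_zeroes_and_renormalizes(self):
        cat = make_catalog(n_random=4, seed=10)
        mix = 0.95 * cat["SBS_R1"] + 0.05 * cat["SBS_R2"]
        exp = refit_exposures(mix, cat, min_weight=0.10)
        assert exp.weights["SBS_R2"] == 0.0
        assert sum(exp.weights.values()) == pytest.approx(1.0)

    def test_reconstruction_beats_best_single_signature(self):
        cat = make_catalog(n_random=5, seed=11, include={"pole": pole_like_signature()})
        target = 0.6 * cat["pole"] + 0.4 * cat["SBS_R2"]
        exp = refit_exposures(target, cat)
        w = np.array([exp.weights[n] for n in cat.names])
        recon_err = np.linalg.norm(target - cat.matrix @ (w * 1.0))
        best_single = min(
            np.linalg.norm(target - cat.matrix[:, j]) for j in range(len(cat.names))
        )
        assert recon_err <= best_single + 1e-12

    def test_recovery_from_simulated_spectrum(self):
        sig = pole_like_signature()
        cat = make_catalog(n_random=5, seed=12, include={"pole": sig})
        spec = Spectrum96(sig, normalized=True)
        exp = refit_exposures(spec, cat)
        assert exp.weights["pole"] == pytest.approx(1.0, abs=1e-6)
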