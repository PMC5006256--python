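import math

import numpy as np
import pytest

from hextma import (
    CooccurrenceMatrix,
    HexGridSpec,
    SyntheticSpec,
    build_tiling,
    cooccurrence,
    dichotomize,
    entropy_profile,
    generate_case,
    haralick_entropy,
)
from hextma.heterogeneity import (
    HeterogeneityProfile,
    NoTextureSupportError,
    quantize_li,
)

from conftest import make_tiling


def _info_rows(cells, li_values, n=200):
    """Informative tiles at the given axial cells with chosen local LI."""
    return [(q, r, int(round(li * n)), n - int(round(li * n)))
            for (q, r), li in zip(cells, li_values)]


class TestCooccurrence:
    def test_uniform_field_single_diagonal_cell(self):
        rows = _info_rows([(0, 0), (1, 0), (0, 1)], [0.30, 0.30, 0.30])
        m = cooccurrence(make_tiling(rows, min_informative_tiles=1), levels=8)
        assert m.matrix.sum() == pytest.approx(1.0)
        assert m.matrix[2, 2] == pytest.approx(1.0)  # bin 2 = [0.25, 0.375)
        assert np.count_nonzero(m.matrix) == 1

    def test_two_adjacent_tiles_symmetric_halves(self):
        rows = _info_rows([(0, 0), (1, 0)], [0.10, 0.90])
        m = cooccurrence(make_tiling(rows, min_informative_tiles=1), levels=8)
        assert m.matrix[0, 7] == pytest.approx(0.5)
        assert m.matrix[7, 0] == pytest.approx(0.5)

    def test_striped_field_off_diagonal_dominates(self):
        """Alternating-bin stripes: brute-force pair enumeration agrees and
        cross-bin mass exceeds within-bin mass."""
        cells = [(q, r) for q in range(4) for r in range(4)]
        li = [0.1 if q % 2 == 0 else 0.9 for q, r in cells]
        tiling = make_tiling(_info_rows(cells, li), min_informative_tiles=1)
        m = cooccurrence(tiling, levels=8)
        # independent enumeration over the 6-neighbour adjacency
        idx = {c: (0 if v == 0.1 else 7) for c, v in zip(cells, li)}
        brute = np.zeros((8, 8))
        for (q, r), bi in idx.items():
            for dq, dr in ((1, 0), (1, -1), (0, -1)):
                bj = idx.get((q + dq, r + dr))
                if bj is not None:
                    brute[bi, bj] += 1
                    brute[bj, bi] += 1
        brute /= brute.sum()
        assert np.allclose(m.matrix, brute)
        off = m.matrix.sum() - np.trace(m.matrix)
        assert off > np.trace(m.matrix)

    def test_isolated_tiles_raise(self):
        rows = _info_rows([(0, 0), (5, 5)], [0.2, 0.8])
        with pytest.raises(NoTextureSupportError):
            cooccurrence(make_tiling(rows, min_informative_tiles=1))

    def test_insufficient_tiles_excluded(self):
        rows = _info_rows([(0, 0), (1, 0)], [0.2, 0.8]) + [(0, 1, 5, 5)]
        m = cooccurrence(make_tiling(rows, min_informative_tiles=1), levels=8)
        # the 10-nucleus tile (LI 0.5, bin 4) must contribute nothing
        assert m.matrix[4].sum() == 0


class TestEntropy:
    def test_single_cell_zero(self):
        m = np.zeros((8, 8))
        m[3, 3] = 1.0
        assert haralick_entropy(CooccurrenceMatrix(8, m)) == 0.0

    def test_uniform_is_maximal(self):
        g = 4
        m = np.full((g, g), 1.0 / g**2)
        assert haralick_entropy(CooccurrenceMatrix(g, m)) == pytest.approx(
            math.log(g**2)
        )

    def test_two_cell_half_half(self):
        m = np.zeros((8, 8))
        m[0, 1] = m[1, 0] = 0.5
        assert haralick_entropy(CooccurrenceMatrix(8, m)) == pytest.approx(
            math.log(2)
        )

    def test_unnormalized_rejected(self):
        m = np.zeros((8, 8))
        m[0, 0] = 0.7
        with pytest.raises(ValueError):
            haralick_entropy(CooccurrenceMatrix(8, m))

    def test_invariant_to_bin_relabeling(self):
        rng = np.random.default_rng(3)
        m = rng.random((8, 8))
        m = (m + m.T) / 2
        m /= m.sum()
        perm = rng.permutation(8)
        e1 = haralick_entropy(CooccurrenceMatrix(8, m))
        e2 = haralick_entropy(CooccurrenceMatrix(8, m[np.ix_(perm, perm)]))
        assert e1 == pytest.approx(e2)


class TestQuantize:
    def test_edges(self):
        assert list(quantize_li(np.array([0.0, 0.124, 0.125, 0.999, 1.0]), 8)) == [
            0, 0, 1, 7, 7,
        ]


class TestDichotomize:
    def _profiles(self, entropies):
        return [HeterogeneityProfile(f"C{i}", e) for i, e in enumerate(entropies)]

    def test_even_split(self):
        out = dichotomize(self._profiles([1.0, 2.0, 3.0, 4.0]))
        classes = [p.het_class for p in out]
        assert classes == ["homogeneous", "homogeneous",
                           "heterogeneous", "heterogeneous"]

    def test_all_ties_go_homogeneous(self):
        out = dichotomize(self._profiles([1.5] * 5))
        assert all(p.het_class == "homogeneous" for p in out)

    def test_split_sizes_balanced_up_to_ties(self):
        rng = np.random.default_rng(0)
        ent = rng.random(297)
        out = dichotomize(self._profiles(ent))
        n_hom = sum(p.het_class == "homogeneous" for p in out)
        n_het = len(out) - n_hom
        ties = int((ent == np.median(ent)).sum())
        assert abs(n_hom - n_het) <= max(ties, 1)

    def test_requires_two_cases(self):
        with pytest.raises(ValueError):
            dichotomize(self._profiles([1.0]))


def _entropy_at_amplitude(amp, seed):
    spec = SyntheticSpec(
        case_id=f"A{amp}", target_li=0.30, region=(4.0, 4.0),
        field="patchy" if amp > 0 else "constant", amplitude=amp, seed=seed,
    )
    t = build_tiling(generate_case(spec), HexGridSpec(seed=seed))
    return entropy_profile(t).entropy


def test_entropy_monotone_in_heterogeneity_amplitude():
    """Mean entropy increases with the generator's patch amplitude at fixed
    global LI and density (rank correlation over a seeded sweep)."""
    from scipy.stats import spearmanr

    amps = [0.0, 0.08, 0.16, 0.24]
    means = [
        np.mean([_entropy_at_amplitude(a, s) for s in (1, 2, 3, 4)]) for a in amps
    ]
    rho, _ = spearmanr(amps, means)
    assert rho == 1.0


def test_patchy_exceeds_constant_entropy():
    """A patchy case has higher spatial entropy than a constant-probability
    case of identical global LI and density."""
    const = [_entropy_at_amplitude(0.0, s) for s in range(5)]
    patchy = [_entropy_at_amplitude(0.22, s) for s in range(5)]
    assert np.mean(patchy) > np.mean(const)
    assert min(patchy) > max(const)
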