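"""Generator contracts: determinism, scaffold construction, profile model."""
import numpy as np
import pytest

from epichem.errors import ParameterError
from epichem.fingerprints import is_undefined_pair, tanimoto
from epichem.io import write_library
from epichem.scaffolds import bemis_murcko
from epichem.synthetic import (
    SyntheticSpec,
    allocate_scaffold_counts,
    expected_profile_similarity,
    generate_library,
    generate_with_assignments,
    scaffold_templates,
)


def _same_scaffold_similarities(library, assignments):
    """Mean activity-profile Jaccard over defined same-scaffold pairs."""
    a = library.activity_matrix()
    vals = []
    n = len(library)
    for i in range(n):
        for j in range(i + 1, n):
            if assignments[i] == assignments[j] and not is_undefined_pair(a[i], a[j]):
                vals.append(tanimoto(a[i], a[j]))
    return float(np.mean(vals))


def test_deterministic_byte_identical(tmp_path):
    spec = SyntheticSpec(n_compounds=50, seed=7)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_library(generate_library(spec), p1)
    write_library(generate_library(SyntheticSpec(n_compounds=50, seed=7)), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_every_smiles_parses_and_is_canonical(small_synthetic):
    from epichem.io import canonicalize

    for rec in small_synthetic:
        assert canonicalize(rec.smiles) == rec.smiles


def test_scaffold_identity_matches_assignment(assigned_synthetic):
    """Bemis-Murcko extraction on each product recovers its template."""
    library, assignments, templates, _ = assigned_synthetic
    for rec, k in zip(library, assignments):
        assert bemis_murcko(rec.smiles) == templates[k]


def test_maximally_diverse_library_has_all_distinct_scaffolds():
    lib = generate_library(
        SyntheticSpec(n_compounds=40, n_scaffolds=40, scaffold_concentration=0, seed=3)
    )
    scaffolds = {bemis_murcko(s) for s in lib.smiles}
    assert len(scaffolds) == 40


def test_scaffold_counts_are_assigned_exactly(assigned_synthetic):
    library, assignments, _, spec = assigned_synthetic
    expected = allocate_scaffold_counts(
        spec.n_compounds, spec.n_scaffolds, spec.scaffold_concentration
    )
    observed = np.bincount(assignments, minlength=spec.n_scaffolds)
    assert np.array_equal(observed, expected)
    assert observed.sum() == spec.n_compounds and observed.min() >= 1


@pytest.mark.parametrize("concentration", [0.0, 1.0, 2.5])
def test_allocation_sums_and_uniform_case(concentration):
    counts = allocate_scaffold_counts(100, 10, concentration)
    assert counts.sum() == 100
    if concentration == 0.0:
        assert np.array_equal(counts, np.full(10, 10))
    else:
        assert counts[0] == counts.max()  # Zipf head is the largest scaffold


def test_template_capacity_extends_beyond_base_set():
    templates = scaffold_templates(80)
    assert len(set(templates)) == 80
    for t in templates[:5] + templates[-5:]:
        assert bemis_murcko(t) == t


def test_zero_noise_same_scaffold_pairs_identical(assigned_synthetic):
    library, assignments, _, spec = assigned_synthetic
    lib0, asg0, _ = generate_with_assignments(
        SyntheticSpec(
            n_compounds=spec.n_compounds,
            n_scaffolds=spec.n_scaffolds,
            noise_rate=0.0,
            seed=spec.seed,
        )
    )
    assert _same_scaffold_similarities(lib0, asg0) == 1.0


def test_similarity_decays_from_zero_noise():
    """Same-scaffold profile similarity drops as soon as flip noise is added."""
    means = []
    for eps in (0.0, 0.1, 0.3):
        lib, asg, _ = generate_with_assignments(
            SyntheticSpec(n_compounds=60, n_scaffolds=12, noise_rate=eps, seed=11)
        )
        means.append(_same_scaffold_similarities(lib, asg))
    assert means[0] == 1.0 and means[0] > means[1] > means[2]


class TestExpectedProfileSimilarity:
    def test_zero_noise_same_scaffold_is_one(self):
        spec = SyntheticSpec(n_compounds=2, n_scaffolds=1, noise_rate=0.0, seed=0)
        assert expected_profile_similarity(spec, same_scaffold=True) == 1.0

    def test_zero_density_brute_force_enumeration(self):
        """With p=0 every set bit comes from noise; compare to a direct
        4-outcome-per-bit enumeration done independently here."""
        eps, n = 0.2, 5
        spec = SyntheticSpec(
            n_compounds=2, n_scaffolds=1, n_targets=n,
            base_profile_density=0.0, noise_rate=eps, seed=0,
        )
        # brute force over all 4^n joint flip outcomes
        import itertools

        total = p_defined = 0.0
        for bits in itertools.product(range(4), repeat=n):
            prob = 1.0
            inter = union = 0
            for b in bits:  # 0:00 1:10 2:01 3:11
                f1, f2 = b & 1, b >> 1
                prob *= (eps if f1 else 1 - eps) * (eps if f2 else 1 - eps)
                inter += f1 & f2
                union += f1 | f2
            if union:
                total += prob * inter / union
                p_defined += prob
        expected = total / p_defined
        got = expected_profile_similarity(spec, same_scaffold=True)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_agreement_within_3se(self):
        """Direct simulation of the generative model (independent of the
        library machinery) agrees with the closed form at 10,000 pairs."""
        spec = SyntheticSpec(
            n_compounds=2, n_scaffolds=1, base_profile_density=0.1,
            noise_rate=0.1, seed=0,
        )
        rng = np.random.default_rng(123)
        n_pairs, n = 10_000, spec.n_targets
        base = rng.random((n_pairs, n)) < spec.base_profile_density
        x = base ^ (rng.random((n_pairs, n)) < spec.noise_rate)
        y = base ^ (rng.random((n_pairs, n)) < spec.noise_rate)
        inter = (x & y).sum(1)
        union = (x | y).sum(1)
        defined = union > 0
        sims = inter[defined] / union[defined]
        se = sims.std(ddof=1) / np.sqrt(defined.sum())
        closed = expected_profile_similarity(spec, same_scaffold=True)
        assert abs(sims.mean() - closed) < 3 * se

    def test_sparse_profiles_rebound_at_half_noise(self):
        """For sparse base profiles the expectation is *not* monotone in the
        flip rate: at eps=0.5 both profiles are dense coin flips whose Jaccard
        recovers toward 1/3, above its value at eps=0.3.  The closed form
        captures this rebound (for dense profiles, density >= ~0.3, the
        expectation is monotone non-increasing on [0, 0.5])."""
        def e(eps):
            return expected_profile_similarity(
                SyntheticSpec(
                    n_compounds=2, n_scaffolds=1, base_profile_density=0.1,
                    noise_rate=eps, seed=0,
                ),
                same_scaffold=True,
            )

        assert e(0.5) > e(0.3)
        assert e(0.5) == pytest.approx(1 / 3, abs=0.01)

    def test_different_scaffold_below_same_scaffold(self):
        spec = SyntheticSpec(
            n_compounds=2, n_scaffolds=1, base_profile_density=0.3,
            noise_rate=0.1, seed=0,
        )
        assert expected_profile_similarity(spec, False) < expected_profile_similarity(spec, True)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_compounds": 0},
        {"n_compounds": 5, "n_scaffolds": 6},
        {"n_compounds": 5, "noise_rate": 1.5},
        {"n_compounds": 5, "scaffold_concentration": -1},
    ],
)
def test_invalid_spec_rejected(kwargs):
    with pytest.raises(ParameterError):
        SyntheticSpec(**kwargs)
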