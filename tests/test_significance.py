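import numpy as np
import pytest

from slimsig import (
    Alphabet,
    InvalidInputError,
    SequenceDataset,
    UnsupportedMotifError,
    compute_frequencies,
    evaluate_all_schemes,
    evaluate_support,
    p_prime,
    parse_motif,
    sig,
    sig_prime,
    sig_prime_brute_force,
)

LW = Alphabet(("L", "W"))


def _random_dataset(rng, symbols, n_proteins, min_len=4, max_len=12):
    seqs = [
        "".join(rng.choice(list(symbols), size=rng.integers(min_len, max_len + 1)))
        for _ in range(n_proteins)
    ]
    return SequenceDataset.from_strings(seqs, alphabet=Alphabet(tuple(symbols)))


class TestSig:
    def test_worked_example(self):
        assert round(sig(0.1485, 2, 2, 0), 3) == 0.474

    def test_extremes(self):
        assert sig(0.0, 3, 20, 0) == 0.0
        assert sig(1.0, 3, 20, 0) == 1.0

    def test_small_p_survives_large_space(self):
        # 1 - (1-p)^R in naive arithmetic would underflow to 0
        val = sig(1e-18, 5, 20, 0)
        assert val == pytest.approx(1e-18 * 20**5, rel=1e-6)


class TestPPrime:
    def test_worked_example_support_sets(self, worked_dataset, worked_freqs):
        ww = evaluate_support(parse_motif("WW", LW), worked_dataset, worked_freqs)
        wl = evaluate_support(parse_motif("WL", LW), worked_dataset, worked_freqs)
        ll = evaluate_support(parse_motif("LL", LW), worked_dataset, worked_freqs)
        p = ww.p_mu
        assert round(p, 4) == 0.1485
        # the top motif's own p' equals its p exactly
        assert p_prime(ww.p1plus_vector, 4, p) == p
        assert round(p_prime(wl.p1plus_vector, 4, p), 4) == 0.0949
        assert p_prime(ll.p1plus_vector, 4, p) == 0.0

    def test_p_of_one_gives_tail_at_zero(self, worked_dataset, worked_freqs):
        ll = evaluate_support(parse_motif("LL", LW), worked_dataset, worked_freqs)
        assert p_prime(ll.p1plus_vector, 4, 1.0) == 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidInputError):
            p_prime([0.5], 1, 1.5)


class TestSigPrime:
    def test_worked_example_value(self, worked_dataset):
        ww = evaluate_support(parse_motif("WW", LW), worked_dataset)
        report = sig_prime(worked_dataset, ww, "sig_prime")
        assert round(report.value, 3) == 0.302
        assert report.value == pytest.approx(0.302444, abs=5e-7)

    def test_single_factor_product_collapses_to_p_prime(self):
        # one-letter alphabet: a single grouping of multiplicity 1
        ds = SequenceDataset.from_strings(["AAAA", "AAA"], alphabet=Alphabet(("A",)))
        m = parse_motif("AA", ds.alphabet)
        obs = evaluate_support(m, ds)
        report = sig_prime(ds, obs, "sig_prime")
        assert report.value == pytest.approx(obs.p_mu, rel=1e-12)

    @pytest.mark.parametrize("scheme", ["sig_prime", "sig_prime_v"])
    def test_grouped_equals_brute_force_on_random_datasets(self, scheme):
        rng = np.random.default_rng(99)
        for _ in range(8):
            ds = _random_dataset(rng, "LWD", n_proteins=int(rng.integers(2, 6)))
            l = int(rng.integers(1, 4))
            p = float(rng.uniform(0.01, 0.9))
            grouped = _sig_prime_at(ds, l, p, scheme)
            brute = sig_prime_brute_force(ds, l, p, scheme)
            assert grouped == pytest.approx(brute, abs=1e-10)

    def test_grouped_equals_brute_force_with_wildcards(self):
        rng = np.random.default_rng(17)
        ds = _random_dataset(rng, "LW", n_proteins=3, min_len=6, max_len=10)
        p = 0.3
        grouped = _sig_prime_at(ds, 3, p, "sig_prime", x_max=1)
        brute = sig_prime_brute_force(ds, 3, p, "sig_prime", x_max=1)
        assert grouped == pytest.approx(brute, abs=1e-10)

    def test_monotone_in_p(self, worked_dataset):
        values = [
            _sig_prime_at(worked_dataset, 2, p, "sig_prime")
            for p in np.linspace(0.0, 1.0, 25)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_ambiguous_and_anchored_refused(self, worked_dataset):
        amb = evaluate_support(parse_motif("[LW]W", LW), worked_dataset)
        with pytest.raises(UnsupportedMotifError):
            sig_prime(worked_dataset, amb)
        anchored = evaluate_support(parse_motif("^WW", LW), worked_dataset)
        with pytest.raises(UnsupportedMotifError):
            sig_prime(worked_dataset, anchored)


def _sig_prime_at(ds, l, p, scheme, x_max=0):
    """Grouped exact significance at an arbitrary threshold p."""
    import slimsig.significance as sigmod

    groupings = list(sigmod.enumerate_groupings(ds.alphabet, l))
    weights = np.array([g.multiplicity for g in groupings], dtype=float)
    freqs = compute_frequencies(ds)
    log_sum = 0.0
    for span, w_span in sigmod._span_weights(l, x_max).items():
        p1p = sigmod.grouping_p1plus_matrix(ds, groupings, freqs, span)
        tails = sigmod.grouping_tail_matrix(
            p1p, "sig_prime" if scheme == "sig_prime" else "sig_prime_v"
        )
        pp = sigmod._p_prime_from_tails(tails, p)
        if np.any(pp >= 1.0):
            return 1.0
        log_sum += float(np.sum(weights * w_span * np.log1p(-pp)))
    return float(-np.expm1(log_sum))


class TestEvaluateAllSchemes:
    def test_worked_example_grid(self, worked_dataset):
        reports = evaluate_all_schemes(worked_dataset, parse_motif("WW", LW))
        assert round(reports["sig"].value, 3) == 0.474
        assert round(reports["sig_prime"].value, 3) == 0.302
        # identical-length, shared-global-frequency proteins collapse the
        # exact-support schemes onto their binomial counterparts
        assert reports["sig_v"].value == pytest.approx(reports["sig"].value, abs=1e-12)
        assert reports["sig_prime_v"].value == pytest.approx(
            reports["sig_prime"].value, abs=1e-12
        )

    def test_conservativeness_on_random_motifs(self):
        rng = np.random.default_rng(1234)
        for _ in range(6):
            ds = _random_dataset(rng, "LWK", n_proteins=int(rng.integers(2, 6)))
            patterns = {"".join(rng.choice(list("LWK"), size=2)) for _ in range(3)}
            for pat in patterns:
                reports = evaluate_all_schemes(ds, parse_motif(pat, ds.alphabet))
                assert reports["sig"].value >= reports["sig_prime"].value - 1e-12
                assert reports["sig_v"].value >= reports["sig_prime_v"].value - 1e-12
                for scheme in ("sig_prime", "sig_prime_v"):
                    r = reports[scheme]
                    for _, pp, _w in r.factors:
                        assert pp <= r.p * (1 + 1e-12) + 1e-300

    def test_impossible_motif_scores_zero_everywhere(self):
        ds = SequenceDataset.from_strings(
            ["LLLL", "LLL"], alphabet=Alphabet(("L", "W"))
        )
        reports = evaluate_all_schemes(ds, parse_motif("WW", ds.alphabet))
        # W never occurs: p_motif = 0, support 0 => p = 1, all schemes 1
        assert all(r.p == 1.0 and r.value == 1.0 for r in reports.values())

    def test_single_protein_single_letter_closed_form(self):
        ds = SequenceDataset.from_strings(["AAA"], alphabet=Alphabet(("A",)))
        m = parse_motif("A", ds.alphabet)
        reports = evaluate_all_schemes(ds, m)
        # p_motif = 1, p_1+ = 1, k = 1, N = 1: every scheme equals 1
        for r in reports.values():
            assert r.value == pytest.approx(1.0)
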