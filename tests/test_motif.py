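"""PWM scoring, exact p-values, site scanning and selection."""

import numpy as np
import pytest

import enhancerkit as ek
from enhancerkit.motif import (PWM, BindingSite, find_sites, read_fasta,
                               read_pwms, score_window, select_strongest,
                               site_pvalue, write_pwms, write_sites_tsv)
from enhancerkit.utils import revcomp

from oracles import exhaustive_ln_pvalue


def test_background_pwm_scores_zero():
    pwm = PWM("U", np.full((5, 4), 0.25))
    assert score_window(pwm, "ACGTA") == pytest.approx(0.0)
    assert score_window(pwm, "ACGTA", "-") == pytest.approx(0.0)


def test_single_column_consensus_score():
    pwm = PWM("A1", np.array([[1.0, 0, 0, 0]]), pseudocount=0.0)
    assert score_window(pwm, "A") == pytest.approx(np.log(4.0))
    assert score_window(pwm, "C") == -np.inf


def test_minus_strand_scores_reverse_complement():
    rng = np.random.default_rng(11)
    pwm = PWM("R", rng.dirichlet(np.ones(4), size=6))
    for _ in range(100):
        w = "".join(rng.choice(list("ACGT"), 6))
        assert score_window(pwm, w, "+") == pytest.approx(
            score_window(pwm, revcomp(w), "-"), abs=1e-12)


def test_score_window_contract_errors():
    pwm = PWM("U", np.full((4, 4), 0.25))
    with pytest.raises(ValueError):
        score_window(pwm, "ACG")
    with pytest.raises(ValueError):
        score_window(pwm, "ACGX")
    with pytest.raises(ValueError):
        score_window(pwm, "ACGT", "?")


def test_ambiguous_base_is_background_neutral():
    rng = np.random.default_rng(5)
    pwm = PWM("N1", rng.dirichlet(np.ones(4), size=3))
    assert score_window(pwm, "NNN") == pytest.approx(0.0)
    w = "ANG"
    expect = pwm.log_odds[0, 0] + pwm.log_odds[2, 2]
    assert score_window(pwm, w) == pytest.approx(expect)


def test_pvalue_at_minimum_score_is_one():
    rng = np.random.default_rng(3)
    pwm = PWM("M", rng.dirichlet(np.ones(4), size=4))
    assert site_pvalue(pwm, pwm.min_score) == pytest.approx(0.0, abs=1e-9)


def test_pvalue_requires_enough_bins():
    pwm = PWM("B", np.full((3, 4), 0.25))
    with pytest.raises(ValueError):
        site_pvalue(pwm, 0.0, n_bins=50)


@pytest.mark.parametrize("width,seed", [(3, 0), (4, 1), (5, 2)])
def test_pvalue_matches_exhaustive_enumeration(width, seed):
    """DP survival probability agrees with brute force over all 4^W words."""
    rng = np.random.default_rng(seed)
    pwm = PWM("E", rng.dirichlet(np.ones(4) * 2, size=width))
    for _ in range(8):
        word = "".join(rng.choice(list("ACGT"), width))
        s = score_window(pwm, word)
        expect = exhaustive_ln_pvalue(pwm.matrix, pwm.background, s)
        assert site_pvalue(pwm, s) == pytest.approx(expect, abs=0.01)


def test_pvalue_monotone_nonincreasing_in_score():
    rng = np.random.default_rng(9)
    pwm = PWM("Mo", rng.dirichlet(np.ones(4), size=5))
    scores = np.linspace(pwm.min_score, pwm.max_score, 40)
    lps = [site_pvalue(pwm, s) for s in scores]
    assert all(a >= b - 1e-12 for a, b in zip(lps, lps[1:]))


def test_pvalue_of_unique_consensus():
    """A strict consensus PWM has exactly one maximal word: p = 1/4^W."""
    mat = np.array([[0.91, 0.03, 0.03, 0.03]] * 3)
    pwm = PWM("C", np.vstack([mat[0], np.roll(mat[0], 1), mat[0]]))
    assert site_pvalue(pwm, pwm.max_score) == pytest.approx(
        np.log(1 / 64), abs=0.01)


def test_find_sites_planted_consensus(pwms):
    seq, _ = ek.synth_enhancer(pwms, [("BCD", 37, "+")], seed=4, length=200)
    hits = find_sites(pwms["BCD"], seq, -10.0)
    assert [(h.start, h.strand) for h in hits] == [(37, "+")]
    # minus-strand plant yields the same site with flipped strand
    seq2, _ = ek.synth_enhancer(pwms, [("BCD", 37, "-")], seed=4, length=200)
    hits2 = find_sites(pwms["BCD"], seq2, -10.0)
    assert [(h.start, h.strand) for h in hits2] == [(37, "-")]
    assert hits2[0].ln_p <= -10.0


def test_find_sites_empty_and_errors(pwms):
    bcd = pwms["BCD"]
    assert find_sites(bcd, "A" * 50, -10.0) == []
    with pytest.raises(ValueError):
        find_sites(bcd, "", -10.0)
    with pytest.raises(ValueError):
        find_sites(bcd, "ACGT", None)  # shorter than width, no cutoff


def test_find_sites_reverse_complement_invariance(pwms):
    """Scanning the reverse complement mirrors coordinates and strands."""
    pwm = pwms["HB"]
    seq, _ = ek.synth_enhancer(
        pwms, [("HB", 30, "+"), ("HB", 120, "-")], seed=8, length=200)
    fwd = find_sites(pwm, seq, -9.0)
    rev = find_sites(pwm, revcomp(seq), -9.0)
    mirrored = sorted(
        (len(seq) - h.start - h.width, "+-"[h.strand == "+"]) for h in rev)
    assert sorted((h.start, h.strand) for h in fwd) == mirrored


def test_overlapping_hits_keep_better_score():
    # two overlapping candidate windows: the greedy filter keeps one
    mat = np.array([[0.97, 0.01, 0.01, 0.01]] * 4)
    pwm = PWM("AA", mat)
    hits = find_sites(pwm, "CCAAAAACC", -4.0)
    assert len(hits) == 1


def test_select_strongest_ten_sites(pwms):
    plan = [(tf, 25 + 40 * i, "+")
            for i, tf in enumerate(["BCD", "CAD", "HB", "KNI", "KR"])]
    plan += [(tf, 275 + 40 * i, "+")
             for i, tf in enumerate(["BCD", "CAD", "HB", "KNI", "KR"])]
    seq, _ = ek.synth_enhancer(pwms, plan, seed=2, length=500)
    by_tf = {tf: find_sites(p, seq, -9.0) for tf, p in pwms.items()}
    ann = select_strongest(by_tf, k_per_tf=2, sequence_length=len(seq))
    assert len(ann.sites) == 10
    assert all(sum(1 for s in ann.sites if s.tf_name == tf) == 2
               for tf in pwms)
    starts = [s.start for s in ann.sites]
    assert starts == sorted(starts)


def test_select_strongest_warns_when_short():
    s = BindingSite("BCD", 5, "+", 8, 3.0, -9.0)
    with pytest.warns(UserWarning, match="only 1"):
        ann = select_strongest({"BCD": [s]}, k_per_tf=2)
    assert len(ann.sites) == 1


def test_select_strongest_top_k_by_score():
    sites = [BindingSite("KR", st, "+", 8, sc, -9.0)
             for st, sc in [(0, 5.0), (20, 4.0), (40, 3.0)]]
    ann = select_strongest({"KR": sites}, k_per_tf=2)
    assert sorted(s.score for s in ann.sites) == [4.0, 5.0]


def test_select_strongest_idempotent(pwms):
    sites = [BindingSite("CAD", st, "+", 8, sc, -9.0)
             for st, sc in [(0, 5.0), (20, 4.0), (40, 3.0)]]
    once = select_strongest({"CAD": sites}, k_per_tf=2)
    by_tf = {"CAD": once.sites}
    twice = select_strongest(by_tf, k_per_tf=2)
    assert [s.site_id for s in twice.sites] == [s.site_id for s in once.sites]


def test_roles_assigned_from_default_map():
    sites = {tf: [BindingSite(tf, i * 30, "+", 8, 3.0, -9.0)]
             for i, tf in enumerate(["BCD", "CAD", "HB", "KNI", "KR"])}
    with pytest.warns(UserWarning):
        ann = select_strongest(sites, k_per_tf=2)
    roles = {s.tf_name: s.role for s in ann.sites}
    assert roles == {"BCD": "activator", "CAD": "repressor", "HB": "dual",
                     "KNI": "repressor", "KR": "repressor"}


def test_pwm_validation():
    with pytest.raises(ValueError):
        PWM("bad", np.full((4, 3), 1 / 3))
    with pytest.raises(ValueError):
        PWM("bad", np.full((4, 4), 0.25), background=np.array([0, .5, .25, .25]))
    with pytest.raises(ValueError):
        PWM("bad", np.full((4, 4), 0.25), ln_p_cutoff=1.0)
    pwm = PWM.from_counts("c", np.array([[8, 0, 0, 0]] * 4), pseudocount=0.5)
    assert np.allclose(pwm.matrix.sum(axis=1), 1.0)


def test_pwm_io_round_trip(tmp_path, pwms):
    path = tmp_path / "pwms.txt"
    write_pwms(pwms, path)
    back = read_pwms(path)
    assert set(back) == set(pwms)
    for tf in pwms:
        assert np.allclose(back[tf].matrix, pwms[tf].matrix, atol=1e-5)
        assert back[tf].ln_p_cutoff == pwms[tf].ln_p_cutoff


def test_fasta_and_sites_io(tmp_path, pwms):
    fasta = tmp_path / "seqs.fasta"
    seq, ann = ek.synth_enhancer(pwms, [("BCD", 10, "+")], seed=1,
                                 length=120)
    fasta.write_text(f">enh1\n{seq}\n")
    seqs = read_fasta(fasta)
    assert seqs == {"enh1": seq}
    out = tmp_path / "sites.tsv"
    write_sites_tsv(ann, out)
    import pandas as pd
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == ["enhancer_id", "tf", "start", "end",
                                "strand", "score", "ln_p", "role"]
    assert df.iloc[0]["start"] == 10
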