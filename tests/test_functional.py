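"""Functional annotation: junction classes, fusion transcripts, reading
frame vs direct translation, kinase-domain conservation, coiled-coil
scanning, expression z-scores and verdicts."""
from __future__ import annotations

import math
import random

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from kinefuse.annotate import (ARTIFACT_HOMOLOGOUS, ARTIFACT_TRANS_SPLICE,
                               DOMAIN_ABSENT, DOMAIN_COMPLETE,
                               DOMAIN_TRUNCATED, FRAME_IN, FRAME_OUT,
                               FRAME_PROMOTER, JUNCTION_EXON_CRYPTIC,
                               JUNCTION_EXON_EXON, JUNCTION_UNRESOLVED,
                               VERDICT_ARTIFACT, VERDICT_DRIVER,
                               VERDICT_PASSENGER, FusionAnnotation,
                               build_fusion_transcript, check_kinase_domain,
                               classify_junction, classify_verdict,
                               expression_zscore, flag_artifacts,
                               predict_frame)
from kinefuse.annotation import ExpressionMatrix
from kinefuse.coils import CoilsParameters, coils_scan
from kinefuse.config import FilterConfig
from kinefuse.detect import FusionCandidate
from kinefuse.simulate import UTR5_LEN, _junction

from helpers import make_gene

CFG = FilterConfig()


# ---------------------------------------------------------------------------
# fixtures over the simulated annotation (session-scoped via conftest)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sim(scenario):
    return scenario.annotation


@pytest.fixture(scope="module")
def genome(sim):
    return sim.genome


def make_candidate(sim, name5, name3, t_donor, t_acc, n_split=1):
    g5, g3 = sim.genes[name5], sim.genes[name3]
    return FusionCandidate(
        sample_id="S", gene5=g5.gene_model(), gene3=g3.gene_model(),
        n_chimeric=10, n_split=n_split,
        breakpoint5=g5.tpos_to_genomic(t_donor),
        breakpoint3=g3.tpos_to_genomic(t_acc))


# ---------------------------------------------------------------------------
# junction classification
# ---------------------------------------------------------------------------

def test_both_boundaries_exon_exon(sim):
    g5, g3 = sim.genes["GENE001"], sim.genes["GENE002"]
    c = make_candidate(sim, "GENE001", "GENE002",
                       g5.exon_t_start(3) - 1, g3.exon_t_start(2))
    assert classify_junction(c) == JUNCTION_EXON_EXON


def test_one_boundary_exon_cryptic(sim):
    g5, g3 = sim.genes["GENE001"], sim.genes["GENE002"]
    c = make_candidate(sim, "GENE001", "GENE002",
                       g5.exon_t_start(3) - 5, g3.exon_t_start(2))
    assert classify_junction(c) == JUNCTION_EXON_CRYPTIC


def test_no_split_reads_is_unresolved(sim):
    g5, g3 = sim.genes["GENE001"], sim.genes["GENE002"]
    c = FusionCandidate(sample_id="S", gene5=g5.gene_model(),
                        gene3=g3.gene_model(), n_chimeric=25, n_split=0)
    assert classify_junction(c) == JUNCTION_UNRESOLVED


def test_intronic_breakpoints_unresolved():
    ga = make_gene("GA")
    gb = make_gene("GB", exons=((1000, 1100), (1200, 1300)))
    c = FusionCandidate(sample_id="S", gene5=ga, gene3=gb, n_chimeric=10,
                        n_split=1, breakpoint5=250, breakpoint3=1150)
    assert classify_junction(c) == JUNCTION_UNRESOLVED


# ---------------------------------------------------------------------------
# fusion transcript construction
# ---------------------------------------------------------------------------

def test_exon1_exon2_fusion_concatenates_pieces(sim, genome):
    g5, g3 = sim.genes["GENE009"], sim.genes["GENE010"]
    c = make_candidate(sim, "GENE009", "GENE010",
                       g5.exon_t_lens[0] - 1, g3.exon_t_start(2))
    ft = build_fusion_transcript(c, genome)
    # 5' exon 1 then everything of the 3' gene from exon 2, regardless of
    # genomic strands (minus-strand pieces are reverse-complemented)
    assert ft.seq == g5.t_seq[:g5.exon_t_lens[0]] + g3.t_seq[g3.u5:]


def test_promoter_fusion_retains_complete_downstream_cds(sim, genome):
    g5, g3 = sim.genes["GENE009"], sim.genes["GENE010"]
    c = make_candidate(sim, "GENE009", "GENE010",
                       g5.exon_t_lens[0] - 1, g3.exon_t_start(2))
    ft = build_fusion_transcript(c, genome)
    assert ft.five_cds_nt == 0
    assert ft.three_cds_complete
    assert ft.three_cds_retained_nt == g3.cds_len


def test_intronic_breakpoint_aborts_with_error(sim, genome):
    g5, g3 = sim.genes["GENE001"], sim.genes["GENE002"]
    c = FusionCandidate(sample_id="S", gene5=g5.gene_model(),
                        gene3=g3.gene_model(), n_chimeric=10, n_split=1,
                        breakpoint5=g5.exons[0][1] + 5,  # inside intron 1
                        breakpoint3=g3.tpos_to_genomic(g3.exon_t_start(2)))
    from kinefuse.annotate import BreakpointOutsideExon
    with pytest.raises(BreakpointOutsideExon):
        build_fusion_transcript(c, genome)


# ---------------------------------------------------------------------------
# reading frame vs direct translation oracle
# ---------------------------------------------------------------------------

def _translate_to_stop(nt: str) -> tuple[str, bool]:
    pep = str(Seq(nt[:3 * (len(nt) // 3)]).translate())
    return pep.split("*")[0], "*" in pep


def frame_oracle(ft, g5, g3, t_donor, t_acc) -> str:
    """Classify the fusion frame by translating the constructed sequence,
    using only generator ground truth (every gene's CDS starts right after
    its UTR5_LEN-nt 5' UTR and ends at its stop codon)."""
    protein3, _ = _translate_to_stop(g3.t_seq[g3.u5:g3.u5 + g3.cds_len])
    if t_donor < UTR5_LEN:  # 5' side is untranslated only
        if t_acc > g3.u5:
            return FRAME_OUT  # downstream start codon lost
        start = ft.five_len + (g3.u5 - t_acc)
        pep, stopped = _translate_to_stop(ft.seq[start:])
        return FRAME_PROMOTER if (stopped and pep == protein3) else FRAME_OUT
    pep, stopped = _translate_to_stop(ft.seq[UTR5_LEN:])
    # in frame iff the open reading frame from the 5' start codon runs
    # through the junction into the 3' protein's natural carboxy terminus
    if stopped and len(pep) > 10 and protein3.endswith(pep[-10:]):
        return FRAME_IN
    return FRAME_OUT


FRAME_CASES = [
    # (donor exon offset from boundary, acceptor exon, expected)
    (0, 2, FRAME_IN),
    (-1, 2, FRAME_OUT),
    (-2, 2, FRAME_OUT),
    (0, 3, FRAME_IN),     # truncating but still in frame
]


@pytest.mark.parametrize("shift,acc_exon,expected", FRAME_CASES)
def test_frame_prediction_matches_translation(sim, genome, shift, acc_exon,
                                              expected):
    g5, g3 = sim.genes["GENE001"], sim.genes["GENE002"]
    t_donor = g5.exon_t_start(3) - 1 + shift
    t_acc = g3.exon_t_start(acc_exon)
    c = make_candidate(sim, "GENE001", "GENE002", t_donor, t_acc)
    ft = build_fusion_transcript(c, genome)
    status, _ = predict_frame(ft)
    assert status == expected
    assert status == frame_oracle(ft, g5, g3, t_donor, t_acc)


def test_frame_oracle_agrees_on_all_planted_fusions(scenario, genome):
    sim = scenario.annotation
    for pf in scenario.config.planted_fusions:
        if pf.n_split == 0 or pf.role == "homolog_decoy":
            continue
        g5, g3 = sim.genes[pf.gene5], sim.genes[pf.gene3]
        t_donor, t_acc, _, _ = _junction(pf, g5, g3)
        c = make_candidate(sim, pf.gene5, pf.gene3, t_donor, t_acc)
        ft = build_fusion_transcript(c, genome)
        status, _ = predict_frame(ft)
        intent = {"in_frame": FRAME_IN, "out_of_frame": FRAME_OUT,
                  "promoter": FRAME_PROMOTER}[pf.frame_intent]
        assert status == intent
        assert status == frame_oracle(ft, g5, g3, t_donor, t_acc)


def test_partner_contributing_nine_nt_in_frame_three_aa(sim, genome):
    g5, g3 = sim.genes["GENE001"], sim.genes["GENE002"]
    c = make_candidate(sim, "GENE001", "GENE002", g5.u5 + 9 - 1,
                       g3.exon_t_start(2))
    status, contrib = predict_frame(build_fusion_transcript(c, genome))
    assert (status, contrib) == (FRAME_IN, 3)


def test_partner_contributing_ten_nt_is_out_of_frame(sim, genome):
    g5, g3 = sim.genes["GENE001"], sim.genes["GENE002"]
    c = make_candidate(sim, "GENE001", "GENE002", g5.u5 + 10 - 1,
                       g3.exon_t_start(2))
    status, contrib = predict_frame(build_fusion_transcript(c, genome))
    assert status == FRAME_OUT and contrib == 3


# ---------------------------------------------------------------------------
# kinase-domain conservation
# ---------------------------------------------------------------------------

def _kinase_candidate(sim, acc_exon):
    g5, g3 = sim.genes["GENE001"], sim.genes["GENE002"]
    c = make_candidate(sim, "GENE001", "GENE002", g5.exon_t_start(3) - 1,
                       g3.exon_t_start(acc_exon))
    # attach the registry interval as the pipeline would
    plen = g3.cds_len // 3 - 1
    c2aa = g3.exon_t_lens[1] // 3
    c.gene3.is_kinase = True
    c.gene3.kinase_domain = (max(2, c2aa // 2), plen - 5)
    return c


def test_breakpoint_upstream_of_domain_is_complete(sim, genome):
    c = _kinase_candidate(sim, acc_exon=2)
    ft = build_fusion_transcript(c, genome)
    assert check_kinase_domain(ft, c.gene3) == DOMAIN_COMPLETE


def test_breakpoint_inside_domain_is_truncated(sim, genome):
    c = _kinase_candidate(sim, acc_exon=3)
    ft = build_fusion_transcript(c, genome)
    assert check_kinase_domain(ft, c.gene3) == DOMAIN_TRUNCATED


def test_kinase_as_five_prime_partner_keeping_only_utr_is_absent(sim, genome):
    g5, g3 = sim.genes["GENE002"], sim.genes["GENE001"]
    c = make_candidate(sim, "GENE002", "GENE001", g5.exon_t_lens[0] - 1,
                       g3.exon_t_start(2))
    plen = g5.cds_len // 3 - 1
    c.gene5.is_kinase = True
    c.gene5.kinase_domain = (10, plen - 5)
    ft = build_fusion_transcript(c, genome)
    assert check_kinase_domain(ft, c.gene5) == DOMAIN_ABSENT


def test_missing_registry_domain_warns_absent(sim, genome):
    c = _kinase_candidate(sim, acc_exon=2)
    c.gene3.kinase_domain = None
    ft = build_fusion_transcript(c, genome)
    with pytest.warns(UserWarning, match="registry"):
        assert check_kinase_domain(ft, c.gene3) == DOMAIN_ABSENT


def test_domain_status_monotone_in_breakpoint_position(sim, genome):
    g3 = sim.genes["GENE002"]
    order = {DOMAIN_COMPLETE: 0, DOMAIN_TRUNCATED: 1, DOMAIN_ABSENT: 2}
    statuses = []
    for acc_exon in range(2, len(g3.exon_t_lens) + 1):
        c = _kinase_candidate(sim, acc_exon=acc_exon)
        ft = build_fusion_transcript(c, genome)
        statuses.append(order[check_kinase_domain(ft, c.gene3)])
    # moving the acceptor downstream (more of the kinase lost) never
    # improves the status
    assert statuses == sorted(statuses)
    assert statuses[0] == 0 and statuses[-1] >= 1


# ---------------------------------------------------------------------------
# coiled-coil scanning
# ---------------------------------------------------------------------------

IDEAL = "LEELEEE" * 5  # leucines at heptad positions a and d


def coils_oracle(seq, params):
    """Naive enumeration over every window and the 7 heptad registers."""
    n, w = len(seq), params.window
    scores = [0.0] * n
    if n < w:
        return scores
    for start in range(n - w + 1):
        best = 0.0
        for reg in range(7):
            logsum = 0.0
            for i in range(w):
                row = params.propensity_table.get(seq[start + i])
                p = row[(start + i + reg) % 7] if row else 1.0
                logsum += math.log(p)
            best = max(best, math.exp(logsum / w))
        for i in range(start, start + w):
            scores[i] = max(scores[i], best)
    return scores


def test_sequence_shorter_than_window_has_no_motif():
    res = coils_scan("L" * 27, CoilsParameters.default())
    assert res.max_probability == 0.0 and res.intervals == []


def test_ideal_heptad_repeat_scores_high():
    res = coils_scan(IDEAL, CoilsParameters.default())
    assert res.max_probability > 0.9
    assert res.intervals and res.intervals[0] == (0, len(IDEAL))


def test_shuffled_repeat_scores_below_ideal():
    ideal = coils_scan(IDEAL, CoilsParameters.default()).max_probability
    shuffled = list(IDEAL)
    random.Random(4).shuffle(shuffled)
    assert coils_scan("".join(shuffled),
                      CoilsParameters.default()).max_probability < ideal


@pytest.mark.parametrize("seed,length", [(0, 60), (1, 200), (2, 451)])
def test_scan_matches_brute_force_enumeration(seed, length):
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(aas[i] for i in rng.integers(0, 20, size=length))
    params = CoilsParameters.default()
    res = coils_scan(seq, params)
    np.testing.assert_allclose(res.scores, coils_oracle(seq, params),
                               rtol=1e-10)


def test_ideal_repeat_scan_matches_oracle_and_windows():
    params = CoilsParameters.default()
    res = coils_scan(IDEAL, params)
    np.testing.assert_allclose(res.scores, coils_oracle(IDEAL, params),
                               rtol=1e-10)


# ---------------------------------------------------------------------------
# expression z-scores
# ---------------------------------------------------------------------------

def _matrix(values, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values[0]))]
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                      columns=samples)
    cohorts = pd.Series("C", index=samples)
    return ExpressionMatrix(values=df.astype(float), cohorts=cohorts)


def test_zscore_hand_computed_with_unbiased_sd():
    mat = _matrix([[1.0, 2.0, 3.0]])
    assert expression_zscore(mat, "g0", "s2") == pytest.approx(1.0)


def test_all_equal_cohort_gives_zero_with_warning():
    mat = _matrix([[5.0, 5.0, 5.0]])
    with pytest.warns(UserWarning, match="variance"):
        assert expression_zscore(mat, "g0", "s1") == 0.0


def test_planted_outlier_has_highest_zscore():
    rng = np.random.default_rng(9)
    vals = np.exp(rng.normal(1.0, 0.5, size=(1, 20)))
    vals[0, 7] *= 100.0
    mat = _matrix(vals.tolist())
    zs = [expression_zscore(mat, "g0", f"s{i}") for i in range(20)]
    assert int(np.argmax(zs)) == 7
    assert zs[7] >= 3.0


# ---------------------------------------------------------------------------
# artifact flags and verdicts
# ---------------------------------------------------------------------------

def _artifact_candidate(n_split, with_bp=False):
    ga = make_gene("GA")
    gb = make_gene("GB", exons=((1000, 1100), (1200, 1300)))
    return FusionCandidate(sample_id="s7", gene5=ga, gene3=gb, n_chimeric=25,
                           n_split=n_split,
                           breakpoint5=199 if with_bp else None,
                           breakpoint3=1200 if with_bp else None)


def _outlier_matrix():
    vals = np.full((2, 20), 5.0) + np.linspace(0, 1, 20)
    vals[0, 7] = 5000.0  # GA wildly overexpressed in s7
    df = pd.DataFrame(vals, index=["GA", "GB"],
                      columns=[f"s{i}" for i in range(20)])
    return ExpressionMatrix(values=df, cohorts=pd.Series("C", index=df.columns))


def test_homologous_partners_flagged():
    flags = flag_artifacts(_artifact_candidate(2, with_bp=True),
                           JUNCTION_EXON_EXON, None, True, CFG)
    assert flags == {ARTIFACT_HOMOLOGOUS}


def test_trans_splice_requires_full_conjunction():
    mat = _outlier_matrix()
    c = _artifact_candidate(0)
    assert flag_artifacts(c, JUNCTION_UNRESOLVED, mat, False, CFG) == \
        {ARTIFACT_TRANS_SPLICE}
    # the same expression outlier with split support and a clean junction
    c2 = _artifact_candidate(3, with_bp=True)
    assert flag_artifacts(c2, JUNCTION_EXON_EXON, mat, False, CFG) == frozenset()


def test_gene_absent_from_expression_skips_with_warning():
    mat = _outlier_matrix()
    mat.values.index = ["GX", "GY"]
    with pytest.warns(UserWarning, match="absent"):
        flags = flag_artifacts(_artifact_candidate(0), JUNCTION_UNRESOLVED,
                               mat, False, CFG)
    assert flags == frozenset()


def _annotation(junction=JUNCTION_EXON_EXON, frame=FRAME_IN,
                domain=DOMAIN_COMPLETE, artifacts=frozenset()):
    return FusionAnnotation(candidate=_artifact_candidate(2, with_bp=True),
                            junction_class=junction, frame_status=frame,
                            kinase_gene="GB", kinase_domain_status=domain,
                            partner_contrib_aa=12, artifact_flags=artifacts)


def test_verdict_driver_requires_all_criteria():
    assert classify_verdict(_annotation(), True) == VERDICT_DRIVER
    assert classify_verdict(_annotation(frame=FRAME_OUT), True) == VERDICT_PASSENGER
    assert classify_verdict(_annotation(domain=DOMAIN_TRUNCATED), True) == \
        VERDICT_PASSENGER
    assert classify_verdict(_annotation(), False) == VERDICT_PASSENGER
    assert classify_verdict(
        _annotation(artifacts=frozenset({ARTIFACT_HOMOLOGOUS})), True) == \
        VERDICT_ARTIFACT
    assert classify_verdict(_annotation(frame=FRAME_PROMOTER), True) == \
        VERDICT_DRIVER


def test_driver_annotation_invariant_enforced():
    ann = _annotation(frame=FRAME_OUT)
    ann.verdict = VERDICT_DRIVER
    with pytest.raises(ValueError, match="invariant"):
        ann.validate()
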