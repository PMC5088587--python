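"""The synthetic-data generator: determinism, translation consistency,
controlled divergence and planted expression effects."""

import numpy as np
import pandas as pd
import pytest

from tifykit import expression as expr
from tifykit import motifs, simulate
from tifykit.simulate import (
    FamilySimConfig,
    evolve_codons,
    inverse_jukes_cantor,
    simulate_counts,
    simulate_member,
    simulate_qpcr,
    simulate_three_genome_scenario,
)


# ---------------------------------------------------------------------------
# members


def test_member_cds_translates_to_protein(small_config):
    rng = np.random.default_rng(2)
    for sub in ("JAZ", "ZML", "TIFY", "PPD"):
        prot, cds, _ = simulate_member(sub, small_config, rng)
        assert simulate.translate_cds(cds.residues) == prot.residues


def test_member_subfamily_architecture(models, small_config):
    rng = np.random.default_rng(4)
    prot, _, truth = simulate_member("ZML", small_config, rng)
    assert {h.motif for h in truth.hits} == {"TIFY", "CCT", "GATA"}
    arch = motifs.scan_motifs(prot, models)
    assert motifs.classify_subfamily(arch) == "ZML"


def test_member_jas_is_c_terminal_of_tify(small_config):
    rng = np.random.default_rng(5)
    _, _, truth = simulate_member("JAZ", small_config, rng)
    pos = {h.motif: h.start for h in truth.hits}
    assert pos["TIFY"] < pos["Jas"]


def test_member_too_short_for_motifs_errors(small_config):
    from dataclasses import replace

    tiny = replace(small_config, background_length_aa=(30, 30))
    with pytest.raises(ValueError, match="too short"):
        simulate_member("ZML", tiny, np.random.default_rng(0))


def test_member_deterministic_under_seed(small_config):
    a = simulate_member("JAZ", small_config, np.random.default_rng(9))
    b = simulate_member("JAZ", small_config, np.random.default_rng(9))
    assert a[0].residues == b[0].residues
    assert a[1].residues == b[1].residues


# ---------------------------------------------------------------------------
# codon evolution


def test_evolve_zero_targets_identical(rng, small_config):
    _, cds, _ = simulate_member("TIFY", small_config, rng)
    derived, realized = evolve_codons(cds.residues, 0.0, 0.0, rng)
    assert derived == cds.residues
    assert realized.events == []


def test_evolve_realized_ratio_tracks_planted(rng):
    """Realized synonymous / non-synonymous event counts match the planted
    difference budgets."""
    from tifykit.motifs import AMINO_ACIDS
    from tifykit import molevol

    prot = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 400))
    anc = simulate.back_translate(prot, rng)
    S = sum(molevol.ng86_site_counts(anc[i:i + 3])[0] for i in range(0, len(anc), 3))
    derived, realized = evolve_codons(anc, 0.3, 0.1, rng)
    assert realized.n_syn >= int(0.9 * inverse_jukes_cantor(0.3) * S)
    assert realized.n_nonsyn > 0
    # distinct positions: events never collide
    assert len({e[0] for e in realized.events}) == len(realized.events)


def test_evolve_never_creates_stops(rng, small_config):
    from tifykit import molevol

    _, cds, truth = simulate_member("JAZ", small_config, rng)
    derived, _ = evolve_codons(cds.residues, 0.5, 0.25, rng, truth.protected_aa)
    for i in range(0, len(derived), 3):
        assert not molevol.is_stop(derived[i : i + 3])


def test_evolve_respects_protected_positions(rng, small_config):
    prot, cds, truth = simulate_member("JAZ", small_config, rng)
    derived, _ = evolve_codons(cds.residues, 0.4, 0.2, rng, truth.protected_aa)
    derived_prot = simulate.translate_cds(derived)
    for pos in truth.protected_aa:
        assert derived_prot[pos] == prot.residues[pos]


def test_evolve_unreachable_target_errors(rng):
    # a non-zero amino-acid divergence target on a fully protected sequence
    cds = "ATGAAATGGTTTCTC" * 4
    protected = frozenset(range(len(cds) // 3))
    with pytest.raises(ValueError, match="unreachable"):
        evolve_codons(cds, 0.0, 0.5, rng, protected_aa=protected)


def test_evolve_all_trp_has_no_synonymous_sites(rng):
    # tryptophan-only sequences have S = 0: a synonymous divergence target
    # implies a zero difference budget, so the descendant is unchanged
    derived, realized = evolve_codons("TGG" * 5, 0.5, 0.0, rng)
    assert derived == "TGG" * 5
    assert realized.events == []


def test_ks_recovery_over_seeds():
    """Mean estimated Ks over 20 seeds is within 10% of each planted target
    (the core parameter-recovery property)."""
    from tifykit import molevol
    from tifykit.motifs import AMINO_ACIDS

    for target in (0.1, 0.51):
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prot = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 300))
            anc = simulate.back_translate(prot, rng)
            derived, _ = evolve_codons(anc, target, target / 2, rng)
            aln = molevol.thread_codon_alignment(
                prot, simulate.translate_cds(derived), anc, derived
            )
            estimates.append(molevol.kaks(aln).Ks)
        assert np.mean(estimates) == pytest.approx(target, rel=0.10)


# ---------------------------------------------------------------------------
# scenario


def test_scenario_deterministic(small_config):
    a = simulate_three_genome_scenario(small_config)
    b = simulate_three_genome_scenario(small_config)
    for genome in small_config.genomes:
        assert [(r.id, r.residues) for r in a.proteins[genome]] == [
            (r.id, r.residues) for r in b.proteins[genome]
        ]
    pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)


def test_scenario_family_sizes(small_scenario, small_config):
    focal = small_config.genomes[0]
    assert len(small_scenario.proteins[focal]) == sum(
        small_config.n_per_subfamily.values()
    )
    others = [g for g in small_config.genomes if g != focal]
    n_ancestors = sum(small_config.n_per_subfamily.values()) - sum(
        small_config.duplication_pairs.values()
    )
    for g in others:
        assert len(small_scenario.proteins[g]) == n_ancestors


def test_scenario_truth_subfamily_histogram(small_scenario, small_config):
    focal = small_config.genomes[0]
    hist: dict = {}
    for rec in small_scenario.proteins[focal]:
        sub = small_scenario.truth.subfamily[rec.id]
        hist[sub] = hist.get(sub, 0) + 1
    assert hist == small_config.n_per_subfamily


def test_scenario_cds_translate_everywhere(small_scenario):
    for genome in small_scenario.config.genomes:
        for prot, cds in zip(
            small_scenario.proteins[genome], small_scenario.cds[genome]
        ):
            assert simulate.translate_cds(cds.residues) == prot.residues


def test_scenario_planted_paralog_count(small_scenario, small_config):
    assert len(small_scenario.truth.paralog_pairs) == sum(
        small_config.duplication_pairs.values()
    )


def test_branch_ks_three_point_formulas():
    cfg = FamilySimConfig()
    branch = cfg.branch_ks()
    for (a, b), ks in cfg.ortholog_ks.items():
        assert branch[a] + branch[b] == pytest.approx(ks)


# ---------------------------------------------------------------------------
# counts


def test_counts_planted_nesting_and_overlap(small_scenario, small_config):
    cm = small_scenario.counts
    rpkm_df = expr.rpkm(cm)
    control = [s for s in rpkm_df.columns if s.startswith("control")]
    treatments = {
        cond: {
            tp: [f"{cond}_{tp}_r{k + 1}" for k in range(small_config.n_replicates)]
            for tp in small_config.timepoints
        }
        for cond in small_config.conditions
    }
    calls = expr.call_expression(rpkm_df, control, treatments)
    summary = expr.summarize_profile(calls)
    assert summary.response_counts["cold"]["up"] == small_config.n_up["cold"]
    assert summary.response_counts["dehydration"]["up"] == small_config.n_up["dehydration"]
    assert summary.up_overlap[("cold", "dehydration")] == small_config.n_up["dehydration"]


def test_counts_all_fold_one_mostly_none():
    """With no planted effects at dispersion 0.05, at least 90% of genes are
    classified unresponsive."""
    cfg = FamilySimConfig(
        n_up={"dehydration": 0, "cold": 0}, n_down=0, seed=3
    )
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i}" for i in range(24)]
    lengths = pd.Series(720, index=genes)
    cm, _, _ = simulate_counts(cfg, rng, genes, lengths)
    rpkm_df = expr.rpkm(cm)
    control = [s for s in rpkm_df.columns if s.startswith("control")]
    treatments = {
        cond: {tp: [f"{cond}_{tp}_r{k + 1}" for k in range(2)] for tp in cfg.timepoints}
        for cond in cfg.conditions
    }
    calls = expr.call_expression(rpkm_df, control, treatments)
    n_none = sum(
        1 for c in calls if all(r == "none" for r in c.response.values())
    )
    assert n_none >= 0.9 * len(calls)


def test_counts_replicate_correlation(small_scenario):
    """Replicate log RPKM correlates strongly at dispersion 0.05."""
    rpkm_df = expr.rpkm(small_scenario.counts)
    log_rpkm = np.log2(rpkm_df + 0.01)
    r = np.corrcoef(log_rpkm["control_r1"], log_rpkm["control_r2"])[0, 1]
    assert r > 0.9


# ---------------------------------------------------------------------------
# qPCR


def test_qpcr_noise_free_inverts_exactly():
    cfg = FamilySimConfig(qpcr_sigma=0.0)
    rng = np.random.default_rng(0)
    folds = {"g1": {"cold": {"2h": 4.0, "8h": 1.0}}}
    (rec,) = simulate_qpcr(cfg, rng, folds)
    assert expr.ddct_fold(rec, "control", "cold_2h") == pytest.approx(4.0)
    assert expr.ddct_fold(rec, "control", "cold_8h") == pytest.approx(1.0)


def test_qpcr_noisy_folds_near_planted():
    """At sigma=0.1 the mean recovered fold over 100 genes is within 15% of
    the planted induction."""
    cfg = FamilySimConfig(qpcr_sigma=0.1)
    rng = np.random.default_rng(1)
    folds = {f"g{i}": {"cold": {"2h": 4.0}} for i in range(100)}
    records = simulate_qpcr(cfg, rng, folds)
    recovered = [expr.ddct_fold(r, "control", "cold_2h") for r in records]
    assert np.mean(recovered) == pytest.approx(4.0, rel=0.15)


# ---------------------------------------------------------------------------
# end-to-end recovery on the small scenario


def test_small_scenario_end_to_end_recovery(small_scenario, models):
    """The pipeline's primitives recover the planted truth: every subfamily
    label, every paralog pair, and >= 95% of orthologs."""
    from tifykit import homology

    fam = small_scenario
    for rec in fam.all_proteins():
        arch = motifs.scan_motifs(rec, models)
        assert motifs.classify_subfamily(arch) == fam.truth.subfamily[rec.id]
    focal = fam.config.genomes[0]
    assert homology.find_paralogs(fam.proteins[focal]) == sorted(
        fam.truth.paralog_pairs
    )
    g = fam.config.genomes
    pairs = set(
        homology.reciprocal_best_hits(fam.proteins[g[0]], fam.proteins[g[1]])
    )
    truth = set(fam.truth.ortholog_pairs[(g[0], g[1])])
    assert len(pairs & truth) >= 0.95 * len(truth)
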