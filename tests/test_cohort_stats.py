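"""Token tables, the mixed logit, and the supporting statistics."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from mazeline import cohort_stats as cs
from mazeline import synth
from mazeline.disfluency_core import DisfluencyEvent, DType
from mazeline.transcript_io import Activity

from conftest import kendall_tau_b_oracle


def make_event(dtype, cued=False, child="c1", activity=Activity.PLAY):
    return DisfluencyEvent(dtype=dtype, cued=cued, child_id=child, activity=activity)


def make_subjects(*ids_groups, viq=100.0):
    out = {}
    for i, (cid, grp) in enumerate(ids_groups):
        out[cid] = cs.SubjectRecord(cid, grp, viq=viq + i)
    return out


class TestTokenTable:
    def setup_method(self):
        self.subjects = make_subjects(("c1", "ASD"), ("c2", "TD"))
        self.events = [
            make_event(DType.REP),
            make_event(DType.REV),
            make_event(DType.F),
            make_event(DType.FS, cued=True, child="c2"),
        ]

    def test_content_vs_filler_outcomes(self):
        rows = cs.build_token_table(self.events, self.subjects, "content_vs_filler")
        assert [r.outcome for r in rows] == [1, 1, 0, 1]

    def test_rep_vs_rev_keeps_only_those(self):
        rows = cs.build_token_table(self.events, self.subjects, "rep_vs_rev")
        assert [r.outcome for r in rows] == [1, 0]

    def test_false_start_is_a_content_maze_for_cueing(self):
        rows = cs.build_token_table(self.events, self.subjects, "cued_vs_uncued")
        assert len(rows) == 3  # REP, REV, FS included; F excluded
        assert [r.outcome for r in rows] == [0, 0, 1]

    def test_missing_subject_rejected(self):
        with pytest.raises(cs.MissingCovariate):
            cs.build_token_table([make_event(DType.F, child="ghost")], self.subjects, "content_vs_filler")

    def test_module_exclusion(self):
        self.subjects["c2"].ados_module = 2
        rows = cs.build_token_table(
            self.events, self.subjects, "content_vs_filler", exclude_module=2
        )
        assert {r.child_id for r in rows} == {"c1"}

    def test_viq_standardized_over_included_subjects(self):
        rows = cs.build_token_table(self.events, self.subjects, "content_vs_filler")
        by_child = {r.child_id: r.viq_z for r in rows}
        assert np.isclose(sum(by_child.values()), 0.0)
        assert np.isclose(np.std(list(by_child.values()), ddof=1), 1.0)


class TestZTransform:
    def test_unit_spacing(self):
        assert cs.z_transform([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_constant_rejected(self):
        with pytest.raises(cs.ZeroVariance):
            cs.z_transform([2.0, 2.0, 2.0])

    def test_mean_zero_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 9, size=40)
        z = cs.z_transform(x)
        assert abs(z.mean()) < 1e-12 and np.isclose(z.std(ddof=1), 1.0)


class TestKendall:
    def test_perfect_orders(self):
        assert cs.kendall_tau_b([1, 2, 3], [1, 2, 3]).tau_b == pytest.approx(1.0)
        assert cs.kendall_tau_b([1, 2, 3], [3, 2, 1]).tau_b == pytest.approx(-1.0)

    def test_tied_case_matches_enumeration(self):
        res = cs.kendall_tau_b([1, 2, 2, 3], [1, 2, 3, 3])
        assert res.tau_b == pytest.approx(kendall_tau_b_oracle([1, 2, 2, 3], [1, 2, 3, 3]))

    def test_all_tied_rejected(self):
        with pytest.raises(cs.AllTied):
            cs.kendall_tau_b([1, 1, 1], [1, 2, 3])


class TestBH:
    def test_equal_ps_unchanged(self):
        assert cs.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_stepup_hand_example(self):
        assert cs.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=12)
        adj = cs.bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)


class TestWelch:
    def test_identical_samples(self):
        t, dof, p = cs.welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_small_case(self):
        t, dof, p = cs.welch_t([1, 2], [3, 4])
        assert t == pytest.approx(-2.8284271247)
        assert dof == pytest.approx(2.0)

    def test_antisymmetry(self):
        x, y = [1.0, 4, 2, 5], [2.0, 6, 7]
        t1, _, p1 = cs.welch_t(x, y)
        t2, _, p2 = cs.welch_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_rejected(self):
        with pytest.raises(cs.DegenerateSample):
            cs.welch_t([1.0], [2.0, 3.0])


class TestAndersonDarling:
    def test_identical_samples_permutation_p_high(self):
        x = [1.0, 2, 3, 4, 5]
        _, p = cs.anderson_darling_2s(x, list(x), method="permutation", n_resamples=499, seed=0)
        assert p > 0.5

    def test_shift_detected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 50)
        y = rng.normal(3, 1, 50)
        _, p = cs.anderson_darling_2s(x, y)
        assert p < 0.01

    def test_degenerate_rejected(self):
        with pytest.raises(cs.DegenerateSample):
            cs.anderson_darling_2s([1.0, 1.0], [1.0, 1.0])


class TestMatchGroups:
    @staticmethod
    def _cohort(rng, n=14, mu=100.0, outlier=None):
        subs = []
        for g in ("ASD", "TD"):
            for i in range(n):
                subs.append(
                    cs.SubjectRecord(
                        f"{g}{i}", g,
                        viq=float(rng.normal(mu, 10)),
                        covariates={"CA": 6.0 + (i % 5) * 0.5},
                    )
                )
        if outlier:
            subs[0].viq = outlier
        return subs

    def test_matched_cohort_fully_retained(self):
        subs = self._cohort(np.random.default_rng(4))
        res = cs.match_groups(subs, [cs.MatchConstraint("viq", ("ASD", "TD"))])
        assert len(res.retained) == len(subs) and res.satisfied

    def test_planted_outlier_removed_and_self_consistent(self):
        subs = self._cohort(np.random.default_rng(4), outlier=220.0)
        constraints = [cs.MatchConstraint("viq", ("ASD", "TD"))]
        res = cs.match_groups(subs, constraints)
        assert "ASD0" not in res.retained
        # recompute the battery on the returned subset: all p >= threshold
        kept = [s for s in subs if s.child_id in res.retained]
        for c in constraints:
            check = cs._constraint_tests(kept, c, "asymptotic")
            assert check.welch_p >= 0.2 and check.ad_p >= 0.2

    def test_disjoint_distributions_unsatisfiable(self):
        rng = np.random.default_rng(5)
        subs = [
            cs.SubjectRecord(f"A{i}", "ASD", viq=float(rng.normal(60, 2))) for i in range(6)
        ] + [
            cs.SubjectRecord(f"T{i}", "TD", viq=float(rng.normal(140, 2))) for i in range(6)
        ]
        with pytest.raises(cs.Unsatisfiable):
            cs.match_groups(subs, [cs.MatchConstraint("viq", ("ASD", "TD"))])


class TestMixedLogit:
    def test_sum_coded_levels_sum_to_zero(self):
        rows = synth.simulate_token_table(
            synth.TokenTableConfig(n_subjects=30, tokens_per_subject=20, seed=8)
        )
        res = cs.fit_mixed_logit(rows, posthoc=False, lrt_factors=())
        assert abs(sum(v[0] for v in res.group.values())) < 1e-8
        assert abs(sum(v[0] for v in res.activity.values())) < 1e-8

    def test_reduces_to_plain_logit_with_zero_variance(self):
        import statsmodels.api as sm

        rows = synth.simulate_token_table(
            synth.TokenTableConfig(
                n_subjects=300, tokens_per_subject=1, random_intercept_sd=0.0, seed=3
            )
        )
        res = cs.fit_mixed_logit(rows, posthoc=False, lrt_factors=(), fix_sigma=0.0)
        g_levels = cs._level_order({r.group for r in rows}, cs.GROUP_ORDER)
        a_levels = cs._level_order({r.activity for r in rows}, cs.ACTIVITY_ORDER)
        X = np.hstack(
            [
                np.ones((len(rows), 1)),
                cs._sum_code([r.group for r in rows], g_levels),
                np.array([[r.viq_z] for r in rows]),
                cs._sum_code([r.activity for r in rows], a_levels),
            ]
        )
        y = np.array([r.outcome for r in rows], float)
        ref = sm.Logit(y, X).fit(disp=0)
        ours = np.array(
            [res.intercept[0]]
            + [res.group[g][0] for g in g_levels[:-1]]
            + [res.viq[0]]
            + [res.activity[a][0] for a in a_levels[:-1]]
        )
        assert np.abs(ours - ref.params).max() < 1e-3
        assert res.sigma == 0.0

    def test_matches_lme4_reference_fit(self):
        """Independent oracle: glmer (adaptive GH quadrature) on one dataset."""
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript is required for the reference fit"
        rows = synth.simulate_token_table(
            synth.TokenTableConfig(n_subjects=40, tokens_per_subject=30, seed=5)
        )
        res = cs.fit_mixed_logit(rows, posthoc=False, lrt_factors=())
        lines = ["child_id,outcome,group,viq_z,activity"] + [
            f"{r.child_id},{r.outcome},{r.group},{r.viq_z!r},{r.activity}" for r in rows
        ]
        script = textwrap.dedent(
            """
            suppressMessages(library(lme4))
            d <- read.csv("stdin")
            d$group <- factor(d$group, levels=c("ASD","SLI","TD"))
            d$activity <- factor(d$activity,
                levels=c("PLAY","PICTURE","STORY","CONVERSATION"))
            contrasts(d$group) <- contr.sum(3)
            contrasts(d$activity) <- contr.sum(4)
            m <- glmer(outcome ~ group + viq_z + activity + (1|child_id),
                       data=d, family=binomial, nAGQ=25)
            co <- summary(m)$coefficients
            cat(co[,1], co[,2], sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")
            """
        )
        out = subprocess.run(
            [rscript, "-e", script],
            input="\n".join(lines),
            capture_output=True,
            text=True,
            check=True,
        )
        vals = [float(v) for v in out.stdout.split()]
        est_r, se_r, sigma_r, loglik_r = vals[:7], vals[7:14], vals[14], vals[15]
        ours_est = (
            [res.intercept[0], res.group["ASD"][0], res.group["SLI"][0], res.viq[0]]
            + [res.activity[a][0] for a in ("PLAY", "PICTURE", "STORY")]
        )
        ours_se = (
            [res.intercept[1], res.group["ASD"][1], res.group["SLI"][1], res.viq[1]]
            + [res.activity[a][1] for a in ("PLAY", "PICTURE", "STORY")]
        )
        assert np.abs(np.array(ours_est) - est_r).max() < 5e-3
        assert np.abs(np.array(ours_se) - se_r).max() < 5e-3
        assert abs(res.sigma - sigma_r) < 1e-2
        assert abs(res.loglik - loglik_r) < 0.05

    def test_separation_detected(self):
        rows = [
            cs.TokenRow(f"c{i}", 1, "ASD" if i % 2 else "TD", 0.1 * i - 0.5, "PLAY")
            for i in range(10)
        ]
        with pytest.raises(cs.DegenerateSample):
            cs.fit_mixed_logit(rows)

    def test_module2_exclusion_preserves_conclusions(self):
        """Dropping a random tenth of subjects (the module-2 children) must
        not flip the planted group effect's direction or significance."""
        cfg = synth.SynthConfig(
            groups=(
                synth.GroupSpec(
                    "ASD", 12, 95, 18,
                    type_mix={"REP": 0.30, "REV": 0.16, "FS": 0.26, "F": 0.28},
                ),
                synth.GroupSpec(
                    "TD", 12, 117, 13,
                    type_mix={"REP": 0.17, "REV": 0.13, "FS": 0.20, "F": 0.50},
                ),
            ),
            utterances_per_activity=10,
            seed=31,
        )
        transcripts, subjects, _, _ = synth.simulate_cohort(cfg)
        from mazeline.disfluency_core import extract_events

        events = [e for t in transcripts for e in extract_events(t)]
        full = cs.fit_mixed_logit(
            cs.build_token_table(events, subjects, "content_vs_filler"),
            posthoc=False, lrt_factors=("group",),
        )
        reduced = cs.fit_mixed_logit(
            cs.build_token_table(events, subjects, "content_vs_filler", exclude_module=2),
            posthoc=False, lrt_factors=("group",),
        )
        assert full.group["ASD"][0] > full.group["TD"][0]
        assert reduced.group["ASD"][0] > reduced.group["TD"][0]
        assert (full.lrt["group"].p < 0.05) == (reduced.lrt["group"].p < 0.05)
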