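"""Properties of the synthetic study generator."""

import numpy as np
import pytest
from scipy.stats import norm

from smoltpipe.pedigree import UNKNOWN
from smoltpipe.simulate import (
    ModelParams,
    SimConfig,
    SimConfigError,
    breeding_values_mvn,
    breeding_values_recursive,
    simulate_ct_table,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_read_counts,
)


def flat_freqs(value=0.5, n_loci=17):
    return {k: np.full(n_loci, value) for k in ("wild", "farmed", "landlocked")}


class TestPedigree:
    def test_pure_cross_design_counts(self):
        cfg = SimConfig(seed=1, n_families_per_cross={"Wild": 6, "Farmed": 6},
                        offspring_per_family=10, total_offspring=None)
        ped = simulate_pedigree(cfg)
        assert len(set(ped.family)) == 12
        assert int(ped.is_founder.sum()) == 24
        assert sum(r == "offspring" for r in ped.role) == 120

    def test_f2_individuals_have_two_f1_parents(self):
        cfg = SimConfig(seed=2)
        ped = simulate_pedigree(cfg)
        roles = np.array(ped.role)
        crosses = np.array(ped.cross)
        f2 = np.nonzero((roles == "offspring") & (crosses == "F2"))[0]
        assert f2.size > 0
        for i in f2:
            for parent in (ped.sire[i], ped.dam[i]):
                assert ped.role[parent] == "f1"
                # F1 parents are themselves farmed x wild founder crosses
                gp_strains = {ped.strain[ped.sire[parent]], ped.strain[ped.dam[parent]]}
                assert gp_strains == {"wild", "farmed"}

    def test_default_design_emulates_study_scale(self):
        cfg = SimConfig(seed=3)
        ped = simulate_pedigree(cfg)
        offspring = [i for i, r in enumerate(ped.role) if r == "offspring"]
        assert len(offspring) == 669
        assert len(set(ped.family[i] for i in offspring)) == 36

    def test_topological_order_verified_by_traversal(self):
        ped = simulate_pedigree(SimConfig(seed=4))
        for i in range(ped.n):
            for p in (ped.sire[i], ped.dam[i]):
                assert p == UNKNOWN or p < i

    def test_seed_determinism(self):
        a = simulate_pedigree(SimConfig(seed=5)).to_frame()
        b = simulate_pedigree(SimConfig(seed=5)).to_frame()
        assert a.equals(b)

    def test_unknown_cross_label_rejected(self):
        with pytest.raises(SimConfigError, match="unknown cross"):
            SimConfig(seed=1, cross_design=("Wild", "Backcross3"))


class TestGenotypes:
    def test_degenerate_frequencies_fix_founders(self):
        cfg = SimConfig(seed=1, n_families_per_cross={"Wild": 3}, offspring_per_family=5,
                        total_offspring=None, founder_freq_L=flat_freqs(1.0))
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        assert (geno.dosage[ped.is_founder] == 2).all()

    def test_fixed_cross_yields_all_heterozygotes(self):
        freqs = flat_freqs(0.0)
        freqs["farmed"] = np.ones(17)  # L-fixed farmed x A-fixed wild
        cfg = SimConfig(seed=2, n_families_per_cross={"F1-HWF": 4}, offspring_per_family=8,
                        total_offspring=None, founder_freq_L=freqs)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        off = [i for i, r in enumerate(ped.role) if r == "offspring"]
        assert (geno.dosage[off] == 1).all()

    def test_founder_frequency_recovered(self):
        cfg = SimConfig(seed=3, n_families_per_cross={"Wild": 5000},
                        offspring_per_family=1, total_offspring=None,
                        founder_freq_L=flat_freqs(0.5))
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        founders = ped.is_founder
        n_alleles = 2 * int(founders.sum())
        freq = geno.dosage[founders, 0].sum() / n_alleles
        se = np.sqrt(0.25 / n_alleles)
        assert abs(freq - 0.5) < 3 * se

    def test_mendelian_transmission_rate(self):
        """An AL parent transmits each allele half the time."""
        freqs = flat_freqs(0.0)
        freqs["farmed"] = np.ones(17)
        cfg = SimConfig(seed=4, n_families_per_cross={"F2": 60}, offspring_per_family=30,
                        total_offspring=None, founder_freq_L=freqs)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)  # F1 parents are all AL
        off = [i for i, r in enumerate(ped.role) if r == "offspring"]
        # each transmitted haplotype from an AL parent is L with p = 1/2
        transmitted = geno.haplotypes[off].reshape(-1)
        se = np.sqrt(0.25 / transmitted.size)
        assert abs(transmitted.mean() - 0.5) < 3 * se


class TestPhenotypes:
    def make(self, seed, params, n=10_000, fam=None):
        fam = fam or {"Wild": 200}
        cfg = SimConfig(seed=seed, n_families_per_cross=fam, total_offspring=n,
                        founder_freq_L=flat_freqs(0.5), model_params=params)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        return ped, simulate_phenotypes(ped, geno, config=cfg)

    def test_null_model_gives_half_prevalence(self):
        _, ph = self.make(1, ModelParams())
        se = 0.5 / np.sqrt(len(ph))
        assert abs(ph["Y"].mean() - 0.5) < 3 * se

    def test_intercept_sets_prevalence(self):
        alpha = norm.ppf(0.9)
        _, ph = self.make(2, ModelParams(alpha=alpha))
        se = np.sqrt(0.9 * 0.1 / len(ph))
        assert abs(ph["Y"].mean() - 0.9) < 3 * se

    def test_full_sib_concordance_exceeds_unrelated(self):
        _, ph = self.make(3, ModelParams(sigma2_a=1.0), n=6000, fam={"Wild": 300})
        ph = ph.reset_index(drop=True)
        same = []
        for _, grp in ph.groupby("family"):
            y = grp["Y"].to_numpy()
            k = y.sum()
            pairs = len(y) * (len(y) - 1) / 2
            conc = (k * (k - 1) / 2 + (len(y) - k) * (len(y) - k - 1) / 2) / pairs
            same.append(conc)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ph))
        y = ph["Y"].to_numpy()[perm]
        half = len(y) // 2
        unrelated = (y[:half] == y[half : 2 * half]).mean()
        assert np.mean(same) > unrelated

    def test_negative_variance_rejected(self):
        with pytest.raises(SimConfigError):
            ModelParams(sigma2_a=-0.1)

    def test_weight_law_moments(self):
        _, ph = self.make(4, ModelParams())
        w = ph["W"]
        assert abs(w.mean() - 100.0) / 100.0 < 0.02
        assert abs(w.std() / w.mean() - 0.30) < 0.02

    def test_recursive_and_mvn_breeding_values_agree_in_law(self):
        """Both breeding-value paths give var A sigma2_a: compare
        empirical covariance summaries on a small pedigree."""
        cfg = SimConfig(seed=5, n_families_per_cross={"Wild": 10}, offspring_per_family=10,
                        total_offspring=None, founder_freq_L=flat_freqs(0.5))
        ped = simulate_pedigree(cfg)
        reps = 4000
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        rec = np.stack([breeding_values_recursive(ped, 1.0, rng1) for _ in range(reps)])
        mvn = np.stack([breeding_values_mvn(ped, 1.0, rng2) for _ in range(reps)])
        # variance of each individual ~ diag(A) = 1, sib covariance ~ 0.5
        assert np.allclose(rec.var(axis=0).mean(), 1.0, atol=0.05)
        assert np.allclose(mvn.var(axis=0).mean(), 1.0, atol=0.05)
        fam = np.array(ped.family)
        off = np.array(ped.role) == "offspring"
        f0 = np.nonzero(off & (fam == ped.family[np.argmax(off)]))[0][:2]
        cov_rec = np.cov(rec[:, f0[0]], rec[:, f0[1]])[0, 1]
        cov_mvn = np.cov(mvn[:, f0[0]], mvn[:, f0[1]])[0, 1]
        assert abs(cov_rec - 0.5) < 0.1
        assert abs(cov_mvn - 0.5) < 0.1


class TestReadCounts:
    def test_zero_error_aa_truth_no_l_reads(self):
        cfg = SimConfig(seed=1, n_families_per_cross={"Wild": 10}, offspring_per_family=5,
                        total_offspring=None, founder_freq_L=flat_freqs(0.0), seq_error=0.0)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        counts = simulate_read_counts(geno, cfg)
        assert (counts["n_L"] == 0).all()
        assert (counts["n_other"] == 0).all()

    def test_het_truth_half_l_fraction(self):
        freqs = flat_freqs(0.0)
        freqs["farmed"] = np.ones(17)
        cfg = SimConfig(seed=2, n_families_per_cross={"F1-HWF": 40}, offspring_per_family=10,
                        total_offspring=None, founder_freq_L=freqs, seq_error=0.0)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        counts = simulate_read_counts(geno, cfg)
        off_ids = {ped.ids[i] for i, r in enumerate(ped.role) if r == "offspring"}
        het = counts[counts["sample_id"].isin(off_ids)]
        frac = het["n_L"].sum() / (het["n_A"] + het["n_L"]).sum()
        se = 0.5 / np.sqrt((het["n_A"] + het["n_L"]).sum())
        assert abs(frac - 0.5) < 4 * se

    def test_depth_law_moments(self):
        cfg = SimConfig(seed=3, n_families_per_cross={"Wild": 50}, offspring_per_family=10,
                        total_offspring=None, founder_freq_L=flat_freqs(0.5))
        counts = simulate_read_counts(simulate_genotypes(simulate_pedigree(cfg), cfg), cfg)
        depth = counts["n_A"] + counts["n_L"]
        assert abs(depth.mean() - 500) / 500 < 0.02
        # negative binomial variance mean + mean^2/size
        assert abs(depth.var() / (500 + 500**2 / 5) - 1) < 0.1


class TestCtTable:
    def test_structure_and_determinism(self):
        cfg = SimConfig(seed=1)
        ct = simulate_ct_table(cfg)
        assert set(ct["strain"]) == {"Gullspang", "Mowi"}
        assert set(ct["timepoint"]) == {"pre", "post"}
        counts = ct.groupby(["sample_id", "gene"]).size()
        assert (counts == 3).all()
        assert ct.equals(simulate_ct_table(SimConfig(seed=1)))

    def test_noise_free_fold_change_is_exact_ddct(self):
        from smoltpipe.simulate import CtSimParams

        params = CtSimParams(noise_sd=0.0, sample_sd=0.0,
                             fold_changes={"g": {("Mowi", "post"): 2.0}})
        cfg = SimConfig(seed=2, ct=params)
        ct = simulate_ct_table(cfg)
        target = ct[ct["gene"] == "g"]
        post = target[(target["strain"] == "Mowi") & (target["timepoint"] == "post")]["Ct"]
        pre = target[(target["strain"] == "Mowi") & (target["timepoint"] == "pre")]["Ct"]
        assert post.mean() - pre.mean() == pytest.approx(-1.0)  # log2(2)

    def test_injected_outlier_flagged_downstream(self):
        from smoltpipe.expression import replicate_qc

        cfg = SimConfig(seed=3)
        ct = simulate_ct_table(cfg)
        key = ct[(ct["gene"] == "ef1a")].iloc[0]
        mask = (ct["sample_id"] == key["sample_id"]) & (ct["gene"] == "ef1a") & (ct["replicate"] == 1)
        ct.loc[mask, "Ct"] += 5.0
        trip = ct[(ct["sample_id"] == key["sample_id"]) & (ct["gene"] == "ef1a")]
        qc = replicate_qc(trip.sort_values("replicate")["Ct"].to_numpy())
        assert qc.removed_index == [0]
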