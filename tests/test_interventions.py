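import numpy as np
import pytest

from cardiokit import apply, build_model, e3g_intervention, genotype_intervention
from cardiokit.interventions import GateShift, Intervention
from cardiokit.models import maleckar, tnnp
from cardiokit.protocols import clamp_peak_ina


class TestValidation:
    def test_unknown_gate_function(self):
        with pytest.raises(ValueError, match="unknown gate function"):
            GateShift("q_inf", 5.0)

    def test_substitution_not_supported(self):
        with pytest.raises(NotImplementedError):
            GateShift("alpha_m", 0.0, substitute="alpha_h")

    def test_scale_range(self):
        with pytest.raises(ValueError):
            Intervention("bad", current_scales={"I_CaL": 1.5})
        with pytest.raises(ValueError):
            Intervention("bad", current_scales={"I_CaL": 0.0})

    def test_unscalable_current(self):
        with pytest.raises(ValueError):
            Intervention("bad", current_scales={"I_Na": 0.5})

    def test_unknown_genotype_and_family(self):
        with pytest.raises(ValueError):
            genotype_intervention("R222X", "MGTG")
        with pytest.raises(ValueError):
            genotype_intervention("R222Q", "WRONG")

    def test_i141v_has_no_inactivation_shift_to_ablate(self):
        with pytest.raises(ValueError):
            genotype_intervention("I141V", "MGTG", include_inactivation_shift=False)

    def test_family_mismatch_rejected(self, atrial):
        with pytest.raises(ValueError, match="family"):
            apply(atrial, genotype_intervention("R222Q", "TNNP_SANNBZ"))

    def test_double_zygosity_rejected(self, atrial):
        once = apply(atrial, genotype_intervention("R222Q", "MGTG"))
        with pytest.raises(ValueError, match="zygosity"):
            apply(once, genotype_intervention("I141V", "MGTG"))


class TestApplication:
    def test_out_of_place(self, atrial):
        before = atrial.icoef.copy()
        drugged = apply(atrial, e3g_intervention())
        np.testing.assert_array_equal(atrial.icoef, before)
        assert drugged is not atrial
        assert drugged.icoef[9] == pytest.approx(0.8)
        assert drugged.icoef[10] == pytest.approx(0.5)

    def test_heterozygous_mutation_on_one_allele(self, ventricular):
        het = apply(ventricular, genotype_intervention("R222Q", "TNNP_SANNBZ"))
        assert het.icoef[0] == 0.0 and het.icoef[2] == 0.0     # allele A is WT
        assert het.icoef[4] == pytest.approx(6.3)
        assert het.icoef[6] == pytest.approx(6.2)
        assert het.icoef[8] == pytest.approx(0.5)              # equal mixing

    def test_drug_hits_both_alleles(self, ventricular):
        drugged = apply(ventricular, e3g_intervention())
        assert drugged.icoef[2] == drugged.icoef[6] == pytest.approx(6.0)

    def test_order_independence(self, ventricular):
        gen = genotype_intervention("I141V", "TNNP_SANNBZ")
        a = apply(ventricular, [gen, e3g_intervention()])
        b = apply(apply(ventricular, e3g_intervention()), gen)
        np.testing.assert_allclose(a.icoef, b.icoef)


class TestClosedFormEffects:
    def test_e3g_hinf_is_wt_hinf_shifted_pointwise(self, ventricular, atrial):
        """The drugged availability steady state equals the WT curve
        evaluated at V + 6 mV, exactly, on both alleles."""
        from cardiokit.protocols import _na_system
        V = np.linspace(-120.0, 20.0, 57)
        for model, h_inf in ((ventricular, tnnp.h_inf), (atrial, maleckar.h_inf)):
            drug = apply(model, e3g_intervention())
            alleles, gates, _ = _na_system(drug)
            for al in alleles:
                g = gates(V, al)
                hkey = "h" if "h" in g else "h1"
                np.testing.assert_array_equal(g[hkey][0], h_inf(V + 6.0))

    def test_heterozygous_clamp_current_is_mean_of_alleles(self, ventricular):
        """Under voltage clamp the heterozygous current is exactly the mean
        of the all-WT and all-mutant currents (alleles are independent)."""
        het = apply(ventricular, genotype_intervention("I141V", "TNNP_SANNBZ"))
        hom = apply(ventricular,
                    genotype_intervention("I141V", "TNNP_SANNBZ",
                                          zygosity="homozygous"))
        _, (t, i_wt) = clamp_peak_ina(ventricular, -100.0, step_V=-30.0)
        _, (_, i_het) = clamp_peak_ina(het, -100.0, step_V=-30.0)
        _, (_, i_hom) = clamp_peak_ina(hom, -100.0, step_V=-30.0)
        np.testing.assert_allclose(i_het, 0.5 * (i_wt + i_hom), rtol=1e-12,
                                   atol=1e-12)

    def test_genotypes_are_gain_of_function_at_subthreshold_voltage(self):
        """Both mutations increase peak I_Na elicited at -60 mV."""
        for name, fam in (("ventricular_TNNP_epi", "TNNP_SANNBZ"),
                          ("atrial_MGTG", "MGTG")):
            wt = build_model(name)
            p_wt, _ = clamp_peak_ina(wt, -120.0, step_V=-60.0)
            for g in ("R222Q", "I141V"):
                mut = apply(wt, genotype_intervention(g, fam))
                p_mut, _ = clamp_peak_ina(mut, -120.0, step_V=-60.0)
                assert abs(p_mut) > abs(p_wt)
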