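"""Nernst partitioning model and apparent-K estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from mesoplan import (
    CalibrationParams,
    DropletSpec,
    InsufficientDataError,
    MesoSystem,
    PartitionAssay,
    PartitionParams,
    SyntheticAssaySpec,
    aqueous_concentration_ratio,
    bootstrap_K_interval,
    estimate_K,
    final_meso_system,
    fraction_incorporated,
    partition_state,
    simulate_partition_assay,
    suggest_assay_volume,
)
from mesoplan.partition import FLAG_EXCESS_SUPERNATANT, FLAG_UNBOUNDED


def system(w, m=132.0):
    return MesoSystem(mo_mass=m, water_mass=w)


class TestFractionIncorporated:
    def test_no_partitioning_no_incorporation(self):
        assert fraction_incorporated(PartitionParams(K=0), system(400)) == 0.0

    def test_threshold_regimes_at_40pct_water(self):
        # 40 wt% water on 132 µg monoolein is W = 88 µg
        f_hi = fraction_incorporated(PartitionParams(K=25), system(88))
        f_lo = fraction_incorporated(PartitionParams(K=0.1), system(88))
        assert f_hi == pytest.approx(25 * 132 / (25 * 132 + 88), abs=1e-12)
        assert f_hi >= 0.90
        assert f_lo == pytest.approx(0.130, abs=5e-4)
        assert f_lo <= 0.30

    def test_large_K_limit(self):
        assert fraction_incorporated(PartitionParams(K=1e12), system(88)) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_negative_K_rejected(self):
        with pytest.raises(ValidationError):
            PartitionParams(K=-1)

    @given(
        k=st.floats(0.001, 1000),
        w=st.floats(1, 2000),
        m=st.floats(1, 500),
    )
    def test_monotone_in_K_and_water(self, k, w, m):
        f = fraction_incorporated(PartitionParams(K=k), system(w, m))
        assert 0 <= f <= 1
        assert fraction_incorporated(PartitionParams(K=k * 2), system(w, m)) > f
        assert fraction_incorporated(PartitionParams(K=k), system(w * 2, m)) < f

    @given(k=st.floats(25, 1000), w=st.floats(1, 88))
    def test_high_K_incorporation_exceeds_90pct_below_40pct_water(self, k, w):
        # water contents <= 40 wt% on 132 µg MO are W <= 88 µg
        assert fraction_incorporated(PartitionParams(K=k), system(w)) >= 0.9

    @given(k=st.floats(0.0, 0.1), w=st.floats(88, 2000))
    def test_low_K_incorporation_below_30pct_above_40pct_water(self, k, w):
        assert fraction_incorporated(PartitionParams(K=k), system(w)) <= 0.3


class TestAqueousConcentrationRatio:
    def test_ideal_dilution_limit_K0(self, cal):
        spec = DropletSpec(protein_volume=450, screen_volume=450, dilution_factor=4)
        sys40 = final_meso_system(spec, cal, 132)
        assert aqueous_concentration_ratio(
            PartitionParams(K=0), spec, sys40
        ) == pytest.approx(4.0)

    def test_undiluted_K0_is_unity(self, cal):
        spec = DropletSpec(protein_volume=450, screen_volume=450, dilution_factor=1)
        assert aqueous_concentration_ratio(
            PartitionParams(K=0), spec, final_meso_system(spec, cal, 132)
        ) == pytest.approx(1.0)

    def test_formula_chain_K50_undiluted(self, cal):
        spec = DropletSpec(protein_volume=450, screen_volume=450, dilution_factor=1)
        sys_ = final_meso_system(spec, cal, 132)
        assert sys_.water_mass == pytest.approx(396.0)
        f = fraction_incorporated(PartitionParams(K=50), sys_)
        assert f == pytest.approx(0.943, abs=5e-4)
        ratio = aqueous_concentration_ratio(PartitionParams(K=50), spec, sys_)
        # mole-conservation oracle: aqueous protein mass over final volume
        p_total = 1.0
        p_aq = p_total - f * p_total
        assert ratio == pytest.approx(p_aq * 450 / 450, rel=1e-12)
        assert ratio == pytest.approx(0.057, abs=5e-4)

    @given(k=st.floats(0, 500), d=st.floats(1, 10))
    def test_bounded_by_ideal_dilution(self, k, d):
        cal = CalibrationParams(phi=0.88)
        spec = DropletSpec(protein_volume=450, screen_volume=450, dilution_factor=d)
        sys_ = final_meso_system(spec, cal, 132)
        assert aqueous_concentration_ratio(
            PartitionParams(K=k), spec, sys_
        ) <= aqueous_concentration_ratio(PartitionParams(K=0), spec, sys_) + 1e-12

    @given(k=st.floats(0, 500), d=st.floats(1, 10), vp=st.floats(50, 900))
    def test_mass_conservation(self, k, d, vp):
        # lipid-phase protein + aqueous protein = total, exactly
        cal = CalibrationParams(phi=0.88)
        spec = DropletSpec(protein_volume=vp, screen_volume=450, dilution_factor=d)
        sys_ = final_meso_system(spec, cal, 132)
        st_ = partition_state(PartitionParams(K=k), spec, sys_)
        f = st_.fraction_incorporated
        assert f + (1 - f) == pytest.approx(1.0, abs=1e-15)
        assert st_.c_lip * sys_.mo_mass + st_.c_aq * sys_.water_mass == pytest.approx(
            1.0, rel=1e-12
        )
        # molality ratio recovers K whenever both phases hold protein
        if 0 < f < 1:
            assert st_.c_lip / st_.c_aq == pytest.approx(k, rel=1e-9)


class TestEstimateK:
    def test_no_depletion_means_K0(self):
        assay = PartitionAssay(
            sample_conc=16, applied_volume=900, mo_mass=132, supernatant_conc=(16.0,)
        )
        assert estimate_K(assay).k == 0.0

    def test_roundtrip_from_forward_model(self):
        # forward-simulate f at K=50 (f = 6600/7500 = 0.88 -> C_sup/C_0 = 0.12)
        assay = PartitionAssay(
            sample_conc=20.0,
            applied_volume=900,
            mo_mass=132,
            supernatant_conc=(20.0 * 0.12,),
        )
        assert estimate_K(assay).k == pytest.approx(50.0, rel=1e-12)

    def test_zero_supernatant_flags_unbounded(self):
        est = estimate_K(
            PartitionAssay(
                sample_conc=16, applied_volume=900, mo_mass=132,
                supernatant_conc=(0.0,),
            )
        )
        assert math.isinf(est.replicates[0].k_hat)
        assert est.replicates[0].flag == FLAG_UNBOUNDED

    def test_excess_supernatant_clamped_with_flag(self):
        est = estimate_K(
            PartitionAssay(
                sample_conc=16, applied_volume=900, mo_mass=132,
                supernatant_conc=(17.0, 16.0),
            )
        )
        assert est.replicates[0].k_hat == 0.0
        assert est.replicates[0].flag == FLAG_EXCESS_SUPERNATANT

    @pytest.mark.parametrize(
        "k_true", [0.01, 0.1, 1.0, 5.0, 25.0, 50.0, 125.0, 1000.0]
    )
    def test_noiseless_simulate_then_estimate_is_exact(self, k_true):
        volume = suggest_assay_volume(k_true, 132.0)
        assay = simulate_partition_assay(
            SyntheticAssaySpec(
                k_true=k_true, applied_volume=volume, noise_cv=0.0, n_replicates=3
            )
        )
        assert estimate_K(assay).k == pytest.approx(k_true, rel=1e-9)


class TestBootstrap:
    def _assay(self, seed=1):
        return simulate_partition_assay(
            SyntheticAssaySpec(k_true=50, noise_cv=0.05, n_replicates=8, seed=seed)
        )

    def test_interval_contains_truth_for_mild_noise(self):
        lo, hi = bootstrap_K_interval(self._assay(), seed=1)
        assert lo < 50 < hi

    def test_deterministic_given_seed(self):
        assert bootstrap_K_interval(self._assay(), seed=7) == bootstrap_K_interval(
            self._assay(), seed=7
        )

    def test_identical_replicates_zero_width(self):
        assay = PartitionAssay(
            sample_conc=16, applied_volume=900, mo_mass=132,
            supernatant_conc=(2.0, 2.0, 2.0, 2.0),
        )
        lo, hi = bootstrap_K_interval(assay, seed=0)
        assert lo == hi

    def test_too_few_replicates_or_resamples(self):
        small = PartitionAssay(
            sample_conc=16, applied_volume=900, mo_mass=132,
            supernatant_conc=(2.0, 2.1),
        )
        with pytest.raises(InsufficientDataError):
            bootstrap_K_interval(small, seed=0)
        with pytest.raises(InsufficientDataError):
            bootstrap_K_interval(self._assay(), n_resamples=0, seed=0)


def test_suggest_assay_volume_targets_half_depletion():
    # unclipped: W = K*M gives f = 0.5 exactly
    v = suggest_assay_volume(1.0, 132.0)
    assert v == 132.0
    f = fraction_incorporated(PartitionParams(K=1.0), system(v))
    assert f == pytest.approx(0.5)
    assert suggest_assay_volume(0.1, 132.0) == 100.0  # clipped to plate minimum
    assert suggest_assay_volume(125.0, 132.0) == 900.0  # clipped to plate maximum
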