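"""Eshelby/Hill tensors, Mori-Tanaka limits and the three-level array model."""

import numpy as np
import pytest

from lamellae.errors import (
    DegenerateMaterialError,
    InfeasiblePartitionError,
    InvalidParameterError,
)
from lamellae.homogenization import (
    FibrilArrayParams,
    closest_isotropic,
    eshelby_spheroid,
    fibril_array_stiffness,
    hill_polarization_numeric,
    mori_tanaka,
    partition_phases,
)
from lamellae.tensor import StiffnessTensor, isotropic_stiffness


# ------------------------------------------------------------------- Eshelby
@pytest.mark.parametrize("nu", [0.1, 0.28, 0.3, 0.45])
def test_eshelby_sphere_closed_form(nu):
    """Textbook sphere formulas: S1111=(7-5nu)/(15(1-nu)) etc."""
    S = eshelby_spheroid(nu, 1.0)
    s1111 = (7 - 5 * nu) / (15 * (1 - nu))
    s1122 = (5 * nu - 1) / (15 * (1 - nu))
    s1212 = (4 - 5 * nu) / (15 * (1 - nu))
    assert S[0, 0] == pytest.approx(s1111, abs=1e-10)
    assert S[1, 1] == pytest.approx(s1111, abs=1e-10)
    assert S[2, 2] == pytest.approx(s1111, abs=1e-10)
    assert S[0, 1] == pytest.approx(s1122, abs=1e-10)
    assert S[0, 2] == pytest.approx(s1122, abs=1e-10)
    # Mandel shear slots carry the factor 2 relative to the tensor component
    assert S[3, 3] == pytest.approx(2 * s1212, abs=1e-10)
    assert S[5, 5] == pytest.approx(2 * s1212, abs=1e-10)


@pytest.mark.parametrize("nu", [0.2, 0.3])
def test_eshelby_cylinder_limit(nu):
    """A very long prolate spheroid approaches the circular-cylinder forms."""
    S = eshelby_spheroid(nu, 1e6)
    d = 8 * (1 - nu)
    assert S[0, 0] == pytest.approx((5 - 4 * nu) / d, abs=1e-4)
    assert S[0, 1] == pytest.approx((4 * nu - 1) / d, abs=1e-4)
    assert S[0, 2] == pytest.approx(nu / (2 * (1 - nu)), abs=1e-4)
    assert S[2, 2] == pytest.approx(0.0, abs=1e-4)
    assert S[2, 0] == pytest.approx(0.0, abs=1e-4)
    assert S[5, 5] == pytest.approx(2 * (3 - 4 * nu) / d, abs=1e-4)
    assert S[3, 3] == pytest.approx(2 * 0.25, abs=1e-4)


def test_eshelby_minor_symmetry_block_structure():
    S = eshelby_spheroid(0.3, 14.0)
    # axial symmetry about e3: 11 and 22 slots interchangeable
    assert S[0, 0] == pytest.approx(S[1, 1], abs=1e-12)
    assert S[0, 2] == pytest.approx(S[1, 2], abs=1e-12)
    assert S[3, 3] == pytest.approx(S[4, 4], abs=1e-12)
    # no normal-shear coupling for a spheroid aligned with the axes
    assert np.allclose(S[:3, 3:], 0.0, atol=1e-12)
    assert np.allclose(S[3:, :3], 0.0, atol=1e-12)


def test_eshelby_rejects_bad_inputs():
    with pytest.raises(InvalidParameterError):
        eshelby_spheroid(0.5, 2.0)
    with pytest.raises(InvalidParameterError):
        eshelby_spheroid(0.3, 0.5)  # oblate unsupported


@pytest.mark.parametrize("ar", [1.0, 5.0, 14.0, 100.0])
def test_numeric_polarization_matches_closed_form(ar):
    """P from angular integration vs P = S : C^-1 for an isotropic matrix."""
    C = isotropic_stiffness(5.0, 0.3)
    P_num = hill_polarization_numeric(C, ar)
    P_ref = eshelby_spheroid(0.3, ar) @ np.linalg.inv(C.m)
    assert np.allclose(P_num, P_ref, atol=1e-6 * np.linalg.norm(P_ref))


# --------------------------------------------------------------- Mori-Tanaka
def test_mori_tanaka_zero_fraction_returns_matrix():
    Cm = isotropic_stiffness(5.0, 0.3)
    Ci = isotropic_stiffness(110.5, 0.28)
    C = mori_tanaka(Cm, Ci, 0.0, 14.0)
    assert np.allclose(C.m, Cm.m, atol=0)


def test_mori_tanaka_full_fraction_returns_inclusion():
    Cm = isotropic_stiffness(5.0, 0.3)
    Ci = isotropic_stiffness(110.5, 0.28)
    C = mori_tanaka(Cm, Ci, 1.0, 14.0)
    assert np.allclose(C.m, Ci.m, atol=0)


def test_mori_tanaka_equal_phases_is_identity():
    Cm = isotropic_stiffness(42.0, 0.22)
    C = mori_tanaka(Cm, Cm, 0.37, 7.0)
    assert np.allclose(C.m, Cm.m, atol=1e-10)


def test_mori_tanaka_spherical_voids_isotropic_and_bounded():
    mineral = isotropic_stiffness(110.5, 0.28)
    f = 0.3
    C = mori_tanaka(mineral, None, f, 1.0)
    assert C.is_positive_definite()
    # spherical voids in an isotropic matrix keep the composite isotropic
    E, nu = C.isotropic_constants()
    assert np.allclose(C.m, isotropic_stiffness(E, nu).m, atol=1e-8)
    # below the one-phase Voigt bound (Reuss bound is zero for voids)
    evs = np.linalg.eigvalsh(C.m)
    voigt = (1 - f) * mineral.m
    assert evs.max() <= np.linalg.eigvalsh(voigt).max() + 1e-9
    assert evs.min() > 0


def test_mori_tanaka_voids_hashin_shtrikman_bulk_bound():
    """MT for spherical voids must not exceed the HS upper bulk bound."""
    E, nu = 110.5, 0.28
    kappa = E / (3 * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    for f in (0.1, 0.3, 0.6):
        C = mori_tanaka(isotropic_stiffness(E, nu), None, f, 1.0)
        k_eff, _ = C.isotropic_projection_constants()
        k_hs = kappa + f / (-1 / kappa + 3 * (1 - f) / (3 * kappa + 4 * mu))
        assert k_eff <= k_hs + 1e-6
        assert k_eff > 0


def test_mori_tanaka_within_reuss_voigt_bounds():
    Cm = isotropic_stiffness(5.0, 0.3)
    Ci = isotropic_stiffness(110.5, 0.28)
    for f in (0.1, 0.4, 0.8):
        for ar in (1.0, 14.0, 100.0):
            C = mori_tanaka(Cm, Ci, f, ar)
            voigt = f * Ci.m + (1 - f) * Cm.m
            reuss = np.linalg.inv(f * np.linalg.inv(Ci.m) + (1 - f) * np.linalg.inv(Cm.m))
            evs = np.linalg.eigvalsh(C.m)
            assert evs.max() <= np.linalg.eigvalsh(voigt).max() + 1e-8
            assert evs.min() >= np.linalg.eigvalsh(reuss).min() - 1e-8


def test_mori_tanaka_rejects_bad_fraction():
    Cm = isotropic_stiffness(5.0, 0.3)
    with pytest.raises(InvalidParameterError):
        mori_tanaka(Cm, None, 1.2, 1.0)


def test_closest_isotropic_projection_is_idempotent():
    C = isotropic_stiffness(17.0, 0.31)
    assert np.allclose(closest_isotropic(C).m, C.m, atol=1e-10)


# ------------------------------------------------------------------ partition
def test_partition_default_parameters():
    part = partition_phases(FibrilArrayParams())
    assert part.f_min_in_fibril == pytest.approx(0.25 * 0.38 / 0.53, rel=1e-12)
    assert part.f_void_in_ef == pytest.approx(1 - 0.75 * 0.38 / 0.47, rel=1e-12)


def test_partition_zero_mineral():
    part = partition_phases(FibrilArrayParams(phi_mineral=0.0))
    assert part.f_min_in_fibril == 0.0
    assert part.f_void_in_ef == 1.0  # all-void extra-fibrillar space


def test_partition_infeasible_raises():
    # q*phi > f_fibril: more fibril mineral than fibril volume
    with pytest.raises(InfeasiblePartitionError):
        partition_phases(FibrilArrayParams(q_mineral=0.9, f_fibril=0.25, phi_mineral=0.34))
    # (1-q)*phi > 1-f_fibril: extra-fibrillar mineral overflows
    with pytest.raises(InfeasiblePartitionError):
        partition_phases(FibrilArrayParams(q_mineral=0.1, f_fibril=0.75, phi_mineral=0.34))


def test_params_validation_and_defaults():
    p = FibrilArrayParams()
    assert (p.E_collagen, p.nu_collagen) == (5.0, 0.3)
    assert (p.E_mineral, p.nu_mineral) == (110.5, 0.28)
    assert (p.ar_mineral, p.ar_void, p.ar_fibril) == (14.0, 1.0, 100.0)
    assert (p.f_fibril, p.q_mineral, p.phi_mineral) == (0.53, 0.25, 0.38)
    with pytest.raises(InvalidParameterError):
        FibrilArrayParams(phi_mineral=1.2)
    with pytest.raises(InvalidParameterError):
        FibrilArrayParams(ar_mineral=0.5)


def test_params_yaml_round_trip(tmp_path):
    p = FibrilArrayParams(phi_mineral=0.41, q_mineral=0.3)
    path = tmp_path / "params.yaml"
    p.to_yaml(path)
    assert FibrilArrayParams.from_yaml(path) == p


# ------------------------------------------------------------- full chain
def test_array_is_transversely_isotropic_and_stable(array_tensor):
    from lamellae.tensor import check_transverse_isotropy

    assert array_tensor.is_positive_definite()
    assert check_transverse_isotropy(array_tensor, [0, 0, 1]) < 1e-6
    # the fibril axis is stiffer than the transverse plane
    assert array_tensor.young_along([0, 0, 1]) > array_tensor.young_along([1, 0, 0])


def test_array_monotone_in_mineralization():
    phis = [0.24, 0.30, 0.38, 0.45]
    E3 = [
        fibril_array_stiffness(FibrilArrayParams(phi_mineral=p)).young_along([0, 0, 1])
        for p in phis
    ]
    assert all(a < b for a, b in zip(E3, E3[1:]))


def test_array_eshelby_routes_agree(default_params, array_tensor):
    """Isotropized closed-form route vs fully numeric polarization route."""
    C_num = fibril_array_stiffness(default_params, eshelby_method="numeric")
    assert np.allclose(
        C_num.m, array_tensor.m, atol=1e-5 * np.linalg.norm(array_tensor.m)
    )


def test_array_collapses_to_single_mt_when_all_fibril():
    """f_fibril=1, q=1 is a single Mori-Tanaka of mineral in collagen."""
    p = FibrilArrayParams(f_fibril=1.0, q_mineral=1.0, phi_mineral=0.38)
    C = fibril_array_stiffness(p)
    ref = mori_tanaka(
        isotropic_stiffness(5.0, 0.3), isotropic_stiffness(110.5, 0.28), 0.38, 14.0
    )
    assert np.allclose(C.m, ref.m, atol=1e-10)


def test_array_degenerate_foam_raises():
    # phi=0 with q<1 leaves the extra-fibrillar space all void
    with pytest.raises(DegenerateMaterialError):
        fibril_array_stiffness(FibrilArrayParams(phi_mineral=0.0))


def test_foam_stiffness_vanishes_with_mineral():
    """Mineral foam percolation: stiffness -> 0 as the void fraction -> 1."""
    mineral = isotropic_stiffness(110.5, 0.28)
    n1 = np.linalg.norm(mori_tanaka(mineral, None, 0.999, 1.0).m)
    n2 = np.linalg.norm(mori_tanaka(mineral, None, 0.9, 1.0).m)
    assert n1 < 0.02 * np.linalg.norm(mineral.m)
    assert n1 < n2
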