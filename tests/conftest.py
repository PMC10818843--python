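"""Shared fixtures: meshes, the benchmark forward model, and heavy studies.

Session-scoped fixtures hold the expensive objects (forward model with
Jacobian, the finite-difference Jacobian comparison, the accuracy
study) so that unit tests and the acceptance suite share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import eit_smdr as es
from eit_smdr.forward import compute_sensitivity, homogeneous_field, solve_forward

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol16():
    return es.build_protocol(16)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small mesh (<= 1000 elements) for Jacobian-oracle work."""
    mesh = es.build_mesh(radius=1.0, n_electrodes=16, electrode_width=0.05,
                         target_element_count=600)
    assert mesh.n_elements <= 1000
    return mesh


@pytest.fixture(scope="session")
def bench_model():
    """Default desk-scale model: 1 m disk, 16 electrodes, ~2000 elements."""
    return es.build_model(n_elements=2000)


@pytest.fixture(scope="session")
def fd_jacobian(coarse_mesh, protocol16):
    """Analytic sensitivity next to its central finite-difference oracle.

    The oracle perturbs every element conductivity by +/- 1e-6 S/m and
    re-solves the forward problem; it shares no code with
    ``compute_sensitivity`` beyond the forward solver it differentiates.
    """
    mesh = coarse_mesh
    sigma0 = homogeneous_field(mesh, 1.0)
    S = compute_sensitivity(mesh, sigma0, protocol16)
    delta = 1e-6
    fd = np.empty_like(S)
    for e in range(mesh.n_elements):
        sp = sigma0.copy()
        sp[e] += delta
        sm = sigma0.copy()
        sm[e] -= delta
        up = solve_forward(mesh, sp, protocol16).values
        um = solve_forward(mesh, sm, protocol16).values
        fd[:, e] = (up - um) / (2.0 * delta)
    return S, fd


@pytest.fixture(scope="session")
def robustness_sweep(bench_model):
    """Noise sweep over the standard SNR ladder, 12 seeds, both methods."""
    return es.run_noise_sweep(
        cases=["random"],
        methods=("tk", "smdr"),
        snr_list=(70, 65, 60, 55, 50, 40, 30),
        seeds=range(12),
        model=bench_model,
    )


@pytest.fixture(scope="session")
def accuracy_study(bench_model):
    """21 random 1-3-inclusion phantoms at 50/60/70 dB, both methods."""
    return es.run_noise_sweep(
        cases=["random"],
        methods=("tk", "smdr"),
        snr_list=(50, 60, 70),
        seeds=range(21),
        model=bench_model,
    )
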