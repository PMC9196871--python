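"""Shared, expensively computed study objects (session scope).

The acceptance tests and several property tests consume the same paced
cells, strand recordings, vulnerable-window scans and critical-PCL ramps;
computing each once keeps the whole suite inside a desk-scale budget.
"""

import numpy as np
import pytest

from cardioinflam import (PacingProtocol, apd, average_vw, build_strand,
                          critical_pcl, default_parameters, pace, s1_train,
                          solve_strand)
from cardioinflam.inflammation import apply_perturbation, severity_preset

SEVERITIES = (0.0, 0.5, 1.0)


@pytest.fixture(scope="session")
def apd_table():
    """APD90 at 1 Hz for each variant x severity (200-beat steady state)."""
    out = {}
    for sev in SEVERITIES:
        pert = severity_preset(sev)
        for v in ("ENDO", "MID", "EPI"):
            params = apply_perturbation(default_parameters(v), pert)
            tr = pace(params, PacingProtocol(count=200))
            out[(v, sev)] = apd(tr).apd90
    return out


@pytest.fixture(scope="session")
def control_strand():
    return build_strand()


@pytest.fixture(scope="session")
def control_recording(control_strand):
    """One steady 1 Hz beat on the default strand (0.5 ms sampling)."""
    return solve_strand(control_strand, s1_train(1), duration=700.0)


@pytest.fixture(scope="session")
def inflamed_recording():
    return solve_strand(build_strand(severity=1.0), s1_train(1), duration=700.0)


@pytest.fixture(scope="session")
def vw_results():
    """Mean vulnerable-window width per severity (default site subsample)."""
    return {sev: average_vw(build_strand(severity=sev)) for sev in SEVERITIES}


@pytest.fixture(scope="session")
def pcl_results():
    """Critical-PCL ramp results for the control and globally inflamed strand."""
    return {sev: critical_pcl(build_strand(severity=sev)) for sev in (0.0, 1.0)}
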