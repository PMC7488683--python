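"""Seed-reproducible fixture generation for tests and demonstrations.

Bundles are small text artifacts: random valid model specifications, exact
switching-time observations from forward-simulated 3-gene piecewise cycles,
and jittered versions of those observations.  Everything derives from one
integer seed, so two calls with the same seed write identical bundles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .inverse import perturb_observation, switch_times_from_events
from .model_core import HillCircuitSpec, StepCircuitSpec, validate_spec
from .piecewise import exact_step_trajectory

__all__ = ["random_specs", "cycle_observations", "generate_fixtures"]

_TIME_COLUMNS = ("t1", "t5", "t2", "t3", "t4", "T")


def random_specs(seed: int, n_specs: int = 5):
    """Random valid (Hill, step) spec pairs with plausible kinetics."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_specs):
        n = int(rng.integers(1, 6))
        alpha = tuple(np.round(rng.uniform(1.5, 50.0, n), 6))
        beta = tuple(np.round(rng.uniform(0.5, 2.0, n), 6))
        h = tuple(np.round(rng.uniform(1.0, 12.0, n), 6))
        tau = tuple(np.round(rng.uniform(0.0, 2.0, n), 6))
        out.append(
            (
                validate_spec(HillCircuitSpec(n, alpha, beta, h, tau)),
                validate_spec(StepCircuitSpec(n, alpha, beta, tau)),
            )
        )
    return out


def cycle_observations(seed: int, n_obs: int = 10, noise_scale: float = 1e-4):
    """Forward-simulated 3-gene cycles: (alphas, exact times, jittered times)."""
    rng = np.random.default_rng(seed + 1)
    out = []
    for _ in range(n_obs):
        alphas = tuple(np.round(rng.uniform(1.2, 10.0, 3), 6))
        spec = StepCircuitSpec(3, alpha=alphas, beta=1.0, tau=0.0)
        x0 = tuple(rng.uniform(0.2, 1.8, 3))
        _, events = exact_step_trajectory(spec, x0, 120.0, sample_dt=1.0)
        times = switch_times_from_events(events, t_min=60.0)
        noisy = perturb_observation(times, noise_scale, int(rng.integers(2**31)))
        out.append((alphas, times, noisy))
    return out


def generate_fixtures(seed: int, out_dir) -> dict:
    """Write the full fixture bundle under *out_dir*; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    specs = random_specs(seed)
    spec_payload = [
        {
            "n": hill.n, "alpha": hill.alpha, "beta": hill.beta,
            "h": hill.h, "tau": hill.tau, "symmetric": hill.symmetric,
        }
        for hill, _ in specs
    ]
    spec_path = out_dir / "specs.json"
    spec_path.write_text(json.dumps({"seed": seed, "specs": spec_payload}, indent=1))

    obs = cycle_observations(seed)
    header = "alpha1\talpha2\talpha3\t" + "\t".join(_TIME_COLUMNS)

    def row(alphas, times):
        t = times.to_dict()
        return "\t".join(
            [f"{a:.6f}" for a in alphas] + [f"{t[c]:.12f}" for c in _TIME_COLUMNS]
        )

    exact_path = out_dir / "switch_times.tsv"
    exact_path.write_text(
        "\n".join([header] + [row(a, t) for a, t, _ in obs]) + "\n"
    )
    noisy_path = out_dir / "switch_times_noisy.tsv"
    noisy_path.write_text(
        "\n".join([header] + [row(a, tn) for a, _, tn in obs]) + "\n"
    )
    return {
        "specs": spec_path,
        "switch_times": exact_path,
        "switch_times_noisy": noisy_path,
        "seed": seed,
    }
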