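"""Parameter-recovery runs: simulate a condition preset, infer, compare.

The headline multi-state parameters of the tracking analysis were
measured on live-cell data; here they are validated by inversion:
generate step data from a condition preset (whose parameters are the
measured values), run the Gibbs sampler, and check that the posterior
recovers the generating parameters. ``recover_condition`` is the
single entry point used by the validation suite and the acceptance
script.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from nucleotrack.models import MobilityStateModel
from nucleotrack.states import PosteriorSummary, gibbs_infer, summarize
from nucleotrack.synthetic import make_condition_model, simulate_steps

__all__ = ["RecoveryResult", "recover_condition"]


@dataclass
class RecoveryResult:
    condition: str
    model: MobilityStateModel   # generating (ground-truth) parameters
    summary: PosteriorSummary   # posterior recovery
    n_steps: int

    def within(self, kind: str, i: int, j: int | None = None,
               n_sd: float = 3.0, sd_floor: float = 1e-4) -> bool:
        """True when the recovered value sits within ``n_sd`` posterior
        SDs of the generating value (with a small SD floor so an
        ultra-tight posterior cannot fail on a negligible offset)."""
        if kind == "D":
            est, sd, truth = (self.summary.D_mean[i], self.summary.D_sd[i],
                              self.model.D[i])
        elif kind == "pi":
            est, sd, truth = (self.summary.pi_mean[i], self.summary.pi_sd[i],
                              self.model.pi[i])
        elif kind == "T":
            est, sd, truth = (self.summary.T_mean[i, j],
                              self.summary.T_sd[i, j], self.model.T[i, j])
        else:
            raise ValueError(f"unknown kind {kind!r}")
        return bool(abs(est - truth) <= n_sd * max(sd, sd_floor))


def recover_condition(
    condition: str,
    seed: int,
    n_steps: int = 50_000,
    n_iter: int = 2_000,
    k_init: int = 5,
) -> RecoveryResult:
    """Simulate ``n_steps`` from a condition preset and infer its states.

    The data seed and sampler seed are independent substreams of
    ``seed``. Defaults (50,000 steps, 2,000 sweeps, 5 initial states)
    match the validation conditions of the analysis.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    model = make_condition_model(condition)
    steps = simulate_steps(model, n_steps, seed=np.random.default_rng(ss[0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chain = gibbs_infer(steps, n_iter=n_iter, k_init=k_init,
                            seed=np.random.default_rng(ss[1]))
    return RecoveryResult(condition=condition, model=model,
                          summary=summarize(chain), n_steps=len(steps))
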