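"""Synthetic NADH reference curves.

The calibration tier needs activity-evoked relative-NADH time courses as
targets.  The generator below produces curves with the qualitative structure
of slice recordings during a 20 s stimulation: the neuronal mitochondrial
pool shows a biphasic response (an early dip of about -10 % a few seconds
after onset, recovery before the stimulus ends and a small late overshoot),
the astrocytic cytosolic pool a delayed, slow, monophasic rise, and the
tissue signal a declared volume-weighted mixture of the two.  The generating
parameters are returned so that recovery tests have ground truth.

These are synthetic stand-ins for digitized experimental recordings; they
reproduce the shape of the published transients, not any measured noise or
bleaching structure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .calibration import TargetCurves
from .errors import ConfigError

__all__ = ["FixtureSettings", "generate_nadh_fixture"]


@dataclass(frozen=True)
class FixtureSettings:
    """Shape parameters of the synthetic curves (percent and seconds)."""

    dip_pct: float = -10.0      #: depth of the neuronal mitochondrial dip
    dip_time: float = 5.0       #: time of the dip minimum after onset
    overshoot_pct: float = 3.0  #: late neuronal overshoot amplitude
    astro_rise_pct: float = 6.0  #: astrocytic plateau amplitude
    astro_delay: float = 10.0   #: delay before the astrocytic rise
    astro_tau: float = 15.0     #: astrocytic rise time constant
    decay_tau: float = 40.0     #: slow return-to-baseline time constant
    stim_end: float = 20.0      #: stimulation duration
    t_max: float = 90.0         #: extent of the curves
    dt: float = 0.5             #: sampling interval
    noise_sd: float = 0.0       #: additive Gaussian noise (percent)
    seed: int = 0               #: noise seed
    tissue_w_neuron: float = 0.55  #: neuronal weight of the tissue mixture

    def validate(self) -> None:
        if not -50.0 <= self.dip_pct <= 0.0:
            raise ConfigError("dip_pct must lie in [-50, 0]")
        if not 0.0 <= self.overshoot_pct <= 50.0:
            raise ConfigError("overshoot_pct must lie in [0, 50]")
        if not 0.0 <= self.astro_rise_pct <= 50.0:
            raise ConfigError("astro_rise_pct must lie in [0, 50]")
        if min(self.dip_time, self.astro_tau, self.decay_tau, self.dt) <= 0.0:
            raise ConfigError("time constants must be positive")
        if not 0.0 <= self.tissue_w_neuron <= 1.0:
            raise ConfigError("tissue_w_neuron must lie in [0, 1]")


def generate_nadh_fixture(settings: FixtureSettings | None = None) -> tuple[TargetCurves, dict]:
    """Generate synthetic relative-NADH target curves.

    Returns the curves and the ground-truth generating parameters.
    Deterministic for a given seed; with ``noise_sd = 0`` the curves equal
    their analytic generating functions exactly.
    """
    st = settings or FixtureSettings()
    st.validate()
    t = np.arange(0.0, st.t_max + 1e-9, st.dt)

    # neuronal dip: difference of exponentials normalized to the requested
    # depth at the requested time, cut off by recovery during the stimulus
    tau_fall = st.dip_time / 2.0
    tau_rec = st.dip_time * 2.0
    shape = np.exp(-t / tau_rec) - np.exp(-t / tau_fall)
    shape /= np.max(shape)
    neuron = st.dip_pct * shape
    # late overshoot after the stimulation ends
    post = np.clip(t - st.stim_end, 0.0, None)
    neuron = neuron + st.overshoot_pct * (1.0 - np.exp(-post / 5.0)) * np.exp(-post / st.decay_tau)

    # astrocytic delayed monophasic rise, decaying back after the stimulus
    delayed = np.clip(t - st.astro_delay, 0.0, None)
    astro = st.astro_rise_pct * (1.0 - np.exp(-delayed / st.astro_tau))
    astro = astro * np.exp(-np.clip(t - 2.0 * st.stim_end, 0.0, None) / st.decay_tau)

    tissue = st.tissue_w_neuron * neuron + (1.0 - st.tissue_w_neuron) * astro

    curves = {"neuron_mito": neuron, "astro_cyto": astro, "tissue": tissue}
    if st.noise_sd > 0.0:
        rng = np.random.default_rng(st.seed)
        curves = {k: v + rng.normal(0.0, st.noise_sd, size=t.shape) for k, v in curves.items()}
    truth = asdict(st)
    return (
        TargetCurves(t=t, curves=curves, stim_end=st.stim_end, provenance="fixture",
                     meta={"ground_truth": truth}),
        truth,
    )
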