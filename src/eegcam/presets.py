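"""Ready-made cohort specifications for experiments and calibration runs.

``table_cohort_spec`` is the stated world: the study's group sizes and trial
totals with the default class signatures.  The planted/null variants are the
desk-scale experiment worlds used by the recovery and calibration checks:
high signal-to-noise signatures (amplitude about 3x the in-band background
RMS) or no signatures at all, with reduced trial counts for runtime.
"""

from __future__ import annotations

from typing import Dict, Sequence

from .synth import BandSignature, CohortSpec, DEFAULT_GROUP_SIZES

#: amplitude (uV) ~3x the theta/alpha-band RMS of the default 10 uV 1/f background
HIGH_SNR_AMPLITUDE = 12.0

POSTERIOR = ("parietal", "temporal")


def table_cohort_spec(master_seed: int = 0, scale: float = 1.0) -> CohortSpec:
    """The default cohort: study group sizes, trial totals and signatures."""
    return CohortSpec(master_seed=master_seed, scale=scale)


def _uniform_totals(group_sizes: Dict[str, int],
                    trials_per_task: int) -> Dict[str, Dict[str, int]]:
    return {g: {"MSIT": n * trials_per_task, "STMT": n * trials_per_task}
            for g, n in group_sizes.items()}


def planted_cohort_spec(master_seed: int,
                        amplitude: float = HIGH_SNR_AMPLITUDE,
                        trials_per_task: int = 10,
                        group_sizes: Dict[str, int] | None = None,
                        risk_regions: Sequence[str] = POSTERIOR,
                        heldout_amplitude_factor: float = 0.75,
                        amplitude_sd: float = 1.0,
                        per_trial_jitter: float = 1.0,
                        noise_scale: float = 10.0) -> CohortSpec:
    """High-SNR planted-signature cohort for recovery experiments.

    Risk carriers (A+P-) get theta+alpha oscillations of ``amplitude`` over
    ``risk_regions``; non-carriers get no oscillatory signature; the
    held-out group reuses the risk signatures scaled by
    ``heldout_amplitude_factor`` ("similar yet differing").
    """
    gs = dict(group_sizes or DEFAULT_GROUP_SIZES)
    regions = tuple(risk_regions)
    risk = [BandSignature("theta", regions, amplitude, amplitude_sd, per_trial_jitter),
            BandSignature("alpha", regions, amplitude, amplitude_sd, per_trial_jitter)]
    held = [BandSignature(s.band, s.region, s.amplitude * heldout_amplitude_factor,
                          s.amplitude_sd, s.per_trial_jitter) for s in risk]
    return CohortSpec(
        group_sizes=gs,
        trial_totals=_uniform_totals(gs, trials_per_task),
        signatures={"N": [], "A+P-": risk, "A+P+": held},
        noise_scale=noise_scale,
        artifact_rates={"ocular": 0.0, "emg": 0.0},
        master_seed=master_seed,
    )


def null_cohort_spec(master_seed: int, trials_per_task: int = 10,
                     group_sizes: Dict[str, int] | None = None,
                     noise_scale: float = 10.0) -> CohortSpec:
    """Separability control: zero signature amplitude everywhere.

    The training groups are then distributionally identical and downstream
    CV performance must sit at chance.
    """
    gs = dict(group_sizes or DEFAULT_GROUP_SIZES)
    return CohortSpec(
        group_sizes=gs,
        trial_totals=_uniform_totals(gs, trials_per_task),
        signatures={g: [] for g in gs},
        noise_scale=noise_scale,
        artifact_rates={"ocular": 0.0, "emg": 0.0},
        master_seed=master_seed,
    )
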