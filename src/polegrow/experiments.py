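"""End-to-end validation experiments on synthetic scenes.

Each function renders a population with known ground truth, runs the
full measurement pipeline on the images, and returns measured-vs-true
quantities.  They are used both by the test suite and by the
reproduction script, so the numbers reported there come from the same
code path a user would run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pipeline as pl
from . import synthetic as sy
from .poleprofile import fit_gaussian_width
from .pulsechase import ElongationEstimate

__all__ = [
    "RateRecovery",
    "rate_recovery_experiment",
    "septa_recovery_experiment",
    "cap_width_experiment",
    "morphometry_grid_experiment",
    "SEPTA_SCENARIOS",
]

# population presets mirroring the cell-separation phenotypes: the
# aPBP-less mutant shows ~20% of cells with multiple (unresolved) septa,
# the RodA-less mutant ~5%
SEPTA_SCENARIOS = {
    "apbp_null_like": (0.75, 0.05, 0.20),
    "roda_null_like": (0.90, 0.05, 0.05),
}


@dataclass
class RateRecovery:
    rate_per_pole: float
    true_total_rate: float
    estimate: ElongationEstimate

    @property
    def relative_error(self) -> float:
        return (self.estimate.mean_rate - self.true_total_rate) / self.true_total_rate

    @property
    def covered(self) -> bool:
        return (
            abs(self.estimate.mean_rate - self.true_total_rate)
            <= 2 * self.estimate.se_rate
        )


def rate_recovery_experiment(
    rate_per_pole: float,
    n_cells: int = 150,
    seed: int = 0,
    t_initial: float = 20.0,
    t_final: float = 120.0,
    pulse_end: float = 6.0,
) -> RateRecovery:
    """Simulate a pulse-chase time lapse and re-measure the elongation rate.

    Bipolar growth at ``rate_per_pole`` per pole, pulse ending at
    ``pulse_end`` min, imaged at the two fixed time points; the
    population estimate should recover 2 × rate_per_pole.
    """
    extra = 4 * rate_per_pole * t_final + 0.5
    spec = sy.make_strain_scenario(
        "pulse", n_cells, (1.0, 0.0, 0.0), seed=seed, extra_spacing_um=extra
    )
    growth = sy.GrowthParams(
        rate_pole_a=rate_per_pole, rate_pole_b=rate_per_pole, pulse_end=pulse_end
    )
    optics = sy.OpticsParams(seed=seed)
    tl, _ = sy.simulate_pulse_chase(
        spec.geometries, growth, optics, times=(t_initial, t_final)
    )
    frames = {t_initial: tl.frames[0], t_final: tl.frames[1]}
    est = pl.estimate_rate_from_timelapse(
        frames, optics.pixel_size, t_initial, t_final
    )
    return RateRecovery(rate_per_pole, 2 * rate_per_pole, est)


def septa_recovery_experiment(
    fractions: tuple[float, float, float], n_cells: int, seed: int = 0
) -> tuple[dict, dict]:
    """Render a snapshot population with programmed septum-count
    fractions and re-measure them from the label channel.

    Returns (measured percentages, true percentages), keys
    none/one/multiple (plus n in the measured dict).
    """
    spec = sy.make_strain_scenario("septa", n_cells, fractions, seed=seed)
    optics = sy.OpticsParams(seed=seed)
    frames, _ = sy.render_population(
        spec.geometries, None, optics, channels=("phase", "label")
    )
    _, measured = pl.septa_survey(
        frames["phase"], frames["label"], optics.pixel_size
    )
    cats = ["none", "one", "multiple"]
    true_counts = {c: 0 for c in cats}
    for k in spec.septa_counts:
        true_counts[cats[min(k, 2)]] += 1
    true_pct = {c: 100.0 * v / n_cells for c, v in true_counts.items()}
    return measured, true_pct


def cap_width_experiment(
    sigma: float,
    n_cells: int = 100,
    seed: int = 0,
    amplitude: float = 70.0,
) -> float:
    """Fit the width of the population mean pole profile for a polar
    marker of spread ``sigma``.

    The default amplitude of 70 counts over a 100-count background gives
    a peak signal-to-shot-noise ratio of ~5.  The marker pole is chosen
    at random per cell, so brightest-pole alignment is exercised.
    """
    kind = "tip" if sigma <= 0.4 else "broad"
    spec = sy.make_strain_scenario("cap", n_cells, (1.0, 0.0, 0.0), seed=seed)
    optics = sy.OpticsParams(seed=seed)
    cap = sy.CapModel(kind=kind, sigma=sigma, amplitude=amplitude)
    rng = np.random.default_rng(seed)
    poles = ["A" if rng.random() < 0.5 else "B" for _ in spec.geometries]
    frames, _ = sy.render_population(
        spec.geometries, cap, optics, channels=("phase", "cap"), cap_pole=poles
    )
    mp = pl.pole_profile_survey(frames["phase"], frames["cap"], optics.pixel_size)
    return fit_gaussian_width(mp)


def morphometry_grid_experiment(
    lengths=(1.5, 3.0, 6.0),
    widths=(0.8, 1.0, 1.2),
    orientations_deg=(0.0, 30.0, 60.0, 90.0),
) -> tuple[float, float]:
    """Measure noiseless single rods over a length/width/orientation grid.

    Returns the worst absolute length and width errors in µm.
    """
    optics = sy.OpticsParams(psf_sigma=0.0, poisson_gain=0.0, read_noise_sd=0.0)
    worst_l = worst_w = 0.0
    for L in lengths:
        for W in widths:
            for deg in orientations_deg:
                geom = sy.CellGeometry(
                    (4.0, 4.0), np.radians(deg) % np.pi, L, W
                )
                frames, _ = sy.render_population(
                    [geom], None, optics, channels=("phase",), shape=(140, 140)
                )
                cells = pl.segment_and_mesh(frames["phase"], optics.pixel_size)
                assert len(cells) == 1
                mesh = cells[0].mesh
                from .segmentation import mesh_width

                worst_l = max(worst_l, abs(mesh.length - L))
                worst_w = max(worst_w, abs(mesh_width(mesh) - W))
    return worst_l, worst_w
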