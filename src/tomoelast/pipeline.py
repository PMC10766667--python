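"""Composed reconstruction chains.

Mouse chain (2D, single thru-plane component, 1000-1400 Hz):
Gaussian smoothing (0.15 mm) -> 2D Butterworth low-pass (600 1/m, order 1)
-> 8-direction decomposition -> phase-gradient wavenumber -> k-MDEV
compounding; MDEV (|G*|, loss angle) runs on the smoothed/low-passed fields
without directional decomposition.

Human chain (3D, 3 components, 20-35 Hz): Butterworth (200 1/m) -> 3D curl
high-pass -> 20-direction decomposition -> 3D phase gradient -> k-MDEV.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .inversion import (HUMAN_INVERSION, InversionConfig, MOUSE_INVERSION,
                        kmdev_compound_sws, mdev_invert)
from .params import ComplexWaveField, ParamMap
from .preproc import (FilterConfig, HUMAN_FILTERS, MOUSE_FILTERS,
                      butterworth_lowpass, curl_highpass,
                      directional_decompose, gaussian_smooth,
                      phase_gradient_wavenumber)


def preprocess_mouse(field: ComplexWaveField,
                     filters: FilterConfig = MOUSE_FILTERS) -> ComplexWaveField:
    out = gaussian_smooth(field, filters.gauss_sigma_mm)
    return butterworth_lowpass(out, filters.butterworth_cutoff_inv_m,
                               filters.butterworth_order)


def reconstruct_mouse(fields: Sequence[ComplexWaveField],
                      filters: FilterConfig = MOUSE_FILTERS,
                      inversion: InversionConfig = MOUSE_INVERSION,
                      ) -> Dict[str, ParamMap]:
    """Full mouse reconstruction from one wave field per frequency.

    Returns ``{"sws": ..., "gstar": ..., "loss_angle": ...}``, each eroded
    by one voxel from the mask boundary.
    """
    if len(fields) == 0:
        raise ValueError("no wave fields given")
    smoothed = [preprocess_mouse(f, filters) for f in fields]
    entries = []
    for f in smoothed:
        scale = np.max(np.abs(f.values))
        for comp in directional_decompose(f, filters.n_directions):
            if np.max(np.abs(comp.values)) <= 1e-12 * scale:
                continue  # no energy travels in this direction
            kmap, amp = phase_gradient_wavenumber(
                comp, amplitude_floor_fraction=inversion.min_amplitude_fraction)
            entries.append((f.frequency, kmap, amp))
    sws = kmdev_compound_sws(entries, inversion)
    gstar, phi = mdev_invert(smoothed, inversion)
    return {"sws": sws.eroded(1), "gstar": gstar.eroded(1),
            "loss_angle": phi.eroded(1)}


def reconstruct_human(vector_fields: Sequence[Sequence[ComplexWaveField]],
                      filters: FilterConfig = HUMAN_FILTERS,
                      inversion: InversionConfig = HUMAN_INVERSION,
                      ) -> Dict[str, ParamMap]:
    """Human 3D reconstruction from per-frequency 3-component fields.

    ``vector_fields`` is a sequence over frequencies; each element holds the
    three motion components on a common grid.
    """
    if len(vector_fields) == 0:
        raise ValueError("no wave fields given")
    entries = []
    smoothed_all = []
    for comps in vector_fields:
        smoothed = [butterworth_lowpass(c, filters.butterworth_cutoff_inv_m,
                                        filters.butterworth_order)
                    for c in comps]
        curled = curl_highpass(smoothed)
        smoothed_all.extend(s for s in smoothed
                            if np.max(np.abs(s.values)) > 0)
        scale = max(np.max(np.abs(c.values)) for c in curled)
        for c in curled:
            if np.max(np.abs(c.values)) <= 1e-12 * scale:
                continue  # zero component (e.g. along the polarisation axis)
            for comp in directional_decompose(c, filters.n_directions):
                if np.max(np.abs(comp.values)) <= 1e-12 * scale:
                    continue
                kmap, amp = phase_gradient_wavenumber(
                    comp,
                    amplitude_floor_fraction=inversion.min_amplitude_fraction)
                entries.append((c.frequency, kmap, amp))
    sws = kmdev_compound_sws(entries, inversion)
    gstar, phi = mdev_invert(smoothed_all, inversion)
    return {"sws": sws.eroded(1), "gstar": gstar.eroded(1),
            "loss_angle": phi.eroded(1)}
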