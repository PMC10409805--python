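"""End-to-end record generation: parameters -> beats -> 10 s records.

Thin orchestration over the geometry / activation / forward / synthesis
layers: draw parameter samples for a pathology class, build the case
configuration on one of the pooled anatomies, simulate the single-beat
P wave and QRST complex, and synthesize the labeled record triple
(raw, noisy, filtered).  Everything is deterministic in (label, seed,
anatomy pool).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import SynthesisConfig
from .forward import simulate_pwave, simulate_qrst
from .geometry import AnatomyParams, ParameterSample
from .pathology import (AnatomyCache, PathologyLabel, draw_parameter_samples,
                        make_case_config)
from .synthesis import ECGRecord, MVNSpec, synthesize_record


def anatomy_pool(n: int, seed: int = 0) -> list[AnatomyParams]:
    """Deterministic pool of anatomies with moderate size variability.

    Chamber dimensions vary by up to +/-8% around the defaults,
    emulating the role of an anatomical model cohort.
    """
    rng = np.random.default_rng(seed)
    base = AnatomyParams()
    pool = []
    for _ in range(n):
        s = rng.uniform(0.92, 1.08, size=4)
        pool.append(replace(
            base,
            lv_outer=tuple(np.asarray(base.lv_outer) * s[0]),
            rv_outer=tuple(np.asarray(base.rv_outer) * s[1]),
            rv_center=tuple(np.asarray(base.rv_center) * s[1]),
            lv_wall=base.lv_wall * float(np.clip(s[2], 0.95, 1.08)),
            ra_radius=base.ra_radius * s[3],
            la_radius=base.la_radius * s[3],
        ))
    return pool


def generate_record(label: PathologyLabel, sample: ParameterSample,
                    anatomy: AnatomyParams | None = None,
                    anatomy_id: str = "a0",
                    cache: AnatomyCache | None = None,
                    cfg: SynthesisConfig | None = None,
                    mvn: MVNSpec | None = None) -> ECGRecord:
    """Simulate and synthesize one labeled 10 s record."""
    case = make_case_config(label, sample, anatomy=anatomy, cache=cache)
    pwave = simulate_pwave(case)
    qrst = simulate_qrst(case)
    return synthesize_record(
        pwave, qrst, label=label.case_key, seed=sample.seed, cfg=cfg,
        mvn=mvn, avb=case.avb, anatomy_id=anatomy_id,
        provenance={"omega_qrs": sample.omega_qrs,
                    "omega_t": sample.omega_t,
                    "omega_p": sample.omega_p,
                    "omega_mi": sample.omega_mi})


def generate_records(label: PathologyLabel, n: int, seed: int,
                     anatomies: list[AnatomyParams] | None = None,
                     cache: AnatomyCache | None = None,
                     cfg: SynthesisConfig | None = None):
    """Yield ``(sample, anatomy_id, record)`` for ``n`` runs of one case.

    Runs are spread round-robin over the anatomy pool; the Eikonal
    graphs, meshes and template banks are cached across runs.
    """
    anatomies = anatomies or anatomy_pool(3, seed=seed)
    cache = cache or AnatomyCache()
    samples = draw_parameter_samples(label, n, seed)
    for i, sample in enumerate(samples):
        k = i % len(anatomies)
        rec = generate_record(label, sample, anatomy=anatomies[k],
                              anatomy_id=f"a{k}", cache=cache, cfg=cfg)
        yield sample, f"a{k}", rec
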