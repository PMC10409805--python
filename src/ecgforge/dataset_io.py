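"""Dataset persistence: CSV dialect, parameter files, manifest, splits.

Records are stored the way the published database lays them out: two
top-level class folders (``WP2_largeDataset_Noise`` for signals,
``WP2_largeDataset_ParameterFiles`` for provenance), one disease folder
per case (``mi`` split into artery/transmurality sub-folders), a
training / validation / test subset level, and one ``run_*`` folder per
record holding ``*_raw.csv``, ``*_noise.csv`` and ``*_filtered.csv``
(12 rows x 5000 comma-separated samples, mV, lead order I, II, III,
aVR, aVL, aVF, V1-V6) plus ``*_AtrialParameters.txt`` and
``*_VentricularParameters.txt`` key=value files.  Splits are assigned
per anatomical model so no anatomy appears in more than one subset.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import config
from .pathology import all_cases
from .synthesis import ECGRecord

SIGNAL_CLASS = "WP2_largeDataset_Noise"
PARAM_CLASS = "WP2_largeDataset_ParameterFiles"
SPLITS = ("training", "validation", "test")
FLOAT_FMT = "%.6g"


@dataclass
class RunRecord:
    """Paths and provenance of one written run."""

    run_id: str
    label: str
    paths: dict[str, Path]
    anatomy_id: str = ""
    seed: int | None = None


@dataclass
class DatasetManifest:
    """Case -> split -> run assignment with anatomy-disjoint subsets."""

    cases: dict[str, dict[str, list[dict]]]
    anatomy_split: dict[str, str]
    seed: int

    @property
    def total_runs(self) -> int:
        return sum(len(runs) for case in self.cases.values()
                   for runs in case.values())

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed,
                           "anatomy_split": self.anatomy_split,
                           "cases": self.cases}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        return cls(cases=d["cases"], anatomy_split=d["anatomy_split"],
                   seed=d["seed"])


def _case_dir(label: str) -> str:
    """Folder path for a case key ('mi/LCX_0.3' gains ant/post splits
    elsewhere; the folder uses the artery/transmurality name)."""
    return label


def write_record(record: ECGRecord, root: str | Path, run_id: str,
                 split: str = "training") -> RunRecord:
    """Write one record in the published layout.

    Three signal CSVs under the signal class folder and two key=value
    parameter files under the parameter class folder.
    """
    root = Path(root)
    if record.raw.shape != (12, config.RECORD_SAMPLES):
        raise ValueError("record is not 12 x 5000")
    case = _case_dir(record.label)
    sig_dir = root / SIGNAL_CLASS / case / split / run_id
    par_dir = root / PARAM_CLASS / case / split / run_id
    sig_dir.mkdir(parents=True, exist_ok=True)
    par_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, arr in (("raw", record.raw), ("noise", record.noisy),
                      ("filtered", record.filtered)):
        p = sig_dir / f"{run_id}_{kind}.csv"
        np.savetxt(p, arr, fmt=FLOAT_FMT, delimiter=",")
        paths[kind] = p

    prov = record.provenance
    atrial_lines = {"label": record.label, "anatomy_id": record.anatomy_id,
                    "seed": record.seeds.get("record", ""),
                    "snr_db": record.snr_db}
    omega_p = prov.get("omega_p", {})
    for k, v in omega_p.items():
        if k == "cv":
            for r, val in v.items():
                atrial_lines[f"cv.{r}"] = val
        elif k == "shape_coeffs":
            atrial_lines[k] = ",".join(f"{c:.6g}" for c in v)
        else:
            atrial_lines[k] = v
    vent_lines = {"label": record.label, "anatomy_id": record.anatomy_id,
                  "seed": record.seeds.get("record", "")}
    for site, fields_ in prov.get("omega_qrs", {}).items():
        for k, v in fields_.items():
            vent_lines[f"{site}.{k}"] = v
    for k, v in prov.get("omega_t", {}).items():
        vent_lines[k] = v
    if prov.get("omega_mi"):
        for k, v in prov["omega_mi"].items():
            vent_lines[f"mi.{k}"] = v
    for name, lines in (("AtrialParameters", atrial_lines),
                        ("VentricularParameters", vent_lines)):
        p = par_dir / f"{run_id}_{name}.txt"
        with open(p, "w") as fh:
            for k, v in lines.items():
                fh.write(f"{k}={v}\n")
        paths[name] = p
    return RunRecord(run_id=run_id, label=record.label, paths=paths,
                     anatomy_id=record.anatomy_id,
                     seed=record.seeds.get("record"))


def read_signal_csv(path: str | Path, strict: bool = True) -> np.ndarray:
    """Load one signal CSV; validates 12 rows and the sample count.

    ``strict`` enforces the dataset-conformant 5000 samples; permissive
    mode allows any consistent length.
    """
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.shape[0] != 12:
        raise ValueError(f"{path}: expected 12 rows, found {arr.shape[0]}")
    if strict and arr.shape[1] != config.RECORD_SAMPLES:
        raise ValueError(f"{path}: expected {config.RECORD_SAMPLES} samples "
                         f"per lead, found {arr.shape[1]}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{path}: non-finite values")
    return arr


def read_record(run_dir: str | Path, strict: bool = True) -> dict:
    """Load the three signal variants of one run folder."""
    run_dir = Path(run_dir)
    run_id = run_dir.name
    out = {}
    for kind in ("raw", "noise", "filtered"):
        p = run_dir / f"{run_id}_{kind}.csv"
        if not p.exists():
            raise FileNotFoundError(p)
        out[kind] = read_signal_csv(p, strict=strict)
    return out


def read_parameters(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def validate_dataset(root: str | Path) -> list[str]:
    """Dialect conformance check; returns a list of violations."""
    root = Path(root)
    problems = []
    sig_root = root / SIGNAL_CLASS
    if not sig_root.exists():
        return [f"missing signal class folder {sig_root}"]
    run_dirs = sorted(p.parent for p in sig_root.rglob("*_raw.csv"))
    if not run_dirs:
        problems.append("no runs found")
    for rd in run_dirs:
        run_id = rd.name
        try:
            sigs = read_record(rd)
        except (ValueError, FileNotFoundError) as exc:
            problems.append(str(exc))
            continue
        for kind in ("raw", "noise", "filtered"):
            arr = sigs[kind]
            resid = np.abs(arr[0] - arr[1] + arr[2]).max()
            scale = max(np.abs(arr[:3]).max(), 1e-3)
            if resid > 2e-4 + 1e-3 * scale:
                problems.append(f"{rd}/{run_id}_{kind}.csv: Einthoven "
                                f"identity violated ({resid:.2e})")
        rel = rd.relative_to(sig_root)
        par_dir = root / PARAM_CLASS / rel
        for suffix in ("AtrialParameters", "VentricularParameters"):
            p = par_dir / f"{run_id}_{suffix}.txt"
            if not p.exists():
                problems.append(f"missing parameter file {p}")
            elif not read_parameters(p):
                problems.append(f"empty parameter file {p}")
    return problems


# ---------------------------------------------------------------------------
# Manifest construction


def _stable_hash(text: str, seed: int) -> float:
    h = hashlib.sha256(f"{seed}:{text}".encode()).digest()
    return int.from_bytes(h[:8], "big") / 2**64


def build_manifest(n_per_case: int, anatomies: list[str],
                   split_fractions: tuple[float, float, float] = (0.7, 0.15,
                                                                  0.15),
                   seed: int = 0) -> DatasetManifest:
    """Anatomy-disjoint manifest over the 13 cases.

    Anatomies are hashed into training/validation/test with the given
    fractions; runs are assigned round-robin over the anatomies of
    their split.  Deterministic for a fixed seed.
    """
    if len(anatomies) < len(SPLITS):
        raise ValueError("need at least one anatomy per split")
    if not math.isclose(sum(split_fractions), 1.0, rel_tol=1e-6):
        raise ValueError("split fractions must sum to 1")
    edges = np.cumsum(split_fractions)
    anatomy_split = {}
    for a in anatomies:
        u = _stable_hash(a, seed)
        anatomy_split[a] = SPLITS[int(np.searchsorted(edges, u))]
    # guarantee every split is populated
    for i, s in enumerate(SPLITS):
        if s not in anatomy_split.values():
            free = sorted(anatomies,
                          key=lambda a: _stable_hash(a, seed + 1))[i]
            anatomy_split[free] = s
    by_split = {s: [a for a in anatomies if anatomy_split[a] == s]
                for s in SPLITS}
    counts = {s: int(round(n_per_case * f))
              for s, f in zip(SPLITS, split_fractions)}
    counts["training"] += n_per_case - sum(counts.values())

    cases = {}
    rid = 0
    for label in all_cases():
        case = {s: [] for s in SPLITS}
        for s in SPLITS:
            pool = by_split[s]
            for j in range(counts[s]):
                case[s].append({"run_id": f"run_S{rid}",
                                "anatomy_id": pool[j % len(pool)],
                                "seed": (seed * 1000003 + rid) % (2**31 - 1)})
                rid += 1
        cases[label.case_key] = case
    return DatasetManifest(cases=cases, anatomy_split=anatomy_split,
                           seed=seed)
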