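"""Orchestration: simulate -> fit -> discriminate -> report, plus batched
structure measurements, behind one declarative run configuration."""

from __future__ import annotations

import json
import logging
import time
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datasets import KINETIC_CONSTANTS
from .inference_report import analyze_family, summary_table
from .interface_geometry import (
    ContactThresholds,
    angles_at_center,
    atom_distance,
    buried_area,
    chi1,
    contacts,
    docking_angle,
    sasa,
    superpose,
)
from .kinetic_models import CurveFamily, InvalidStateError, RateParameters
from .structure_io import ca_atoms, read_structure, select_chain
from .synthetic_assay import NoiseModel, builtin_designs, generate_family

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_kinetics", "run_geometry", "fetch_structure"]

RCSB_URL = "https://files.rcsb.org/download/{accession}.pdb"


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    designs: list[str] = field(default_factory=lambda: ["plasmin", "kallikrein", "trypsin"])
    inhibitor: str = "textilinin-1"
    schemes: list[str] = field(default_factory=lambda: ["one_step", "two_step"])
    noise_sd: float | None = None  # None -> generator default
    seed: int = 0
    fixed: dict = field(default_factory=dict)  # k_cat / K_m held constant
    structure_jobs: list[dict] = field(default_factory=list)
    output_dir: str = "tightbind_out"

    def validate(self) -> None:
        if not self.schemes:
            raise InvalidStateError("schemes must be non-empty")
        from .kinetic_models import SchemeId

        for s in self.schemes:
            SchemeId.coerce(s)
        if not isinstance(self.seed, int):
            raise InvalidStateError("seed must be an integer")
        builtin = builtin_designs()
        for d in self.designs:
            if d not in builtin and not Path(d).exists():
                raise InvalidStateError(
                    f"design {d!r} is neither a built-in name {sorted(builtin)} "
                    f"nor an existing manifest path"
                )

    def to_dict(self) -> dict:
        return {
            "designs": list(self.designs),
            "inhibitor": self.inhibitor,
            "schemes": list(self.schemes),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "fixed": dict(self.fixed),
            "structure_jobs": [dict(j) for j in self.structure_jobs],
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_or_generate(config: RunConfig, name: str, index: int) -> CurveFamily:
    builtin = builtin_designs()
    if name in builtin:
        design = builtin[name]
        rates = KINETIC_CONSTANTS.get((config.inhibitor, name))
        if rates is None:
            raise InvalidStateError(
                f"no reference rate constants for {config.inhibitor!r} vs {name!r}"
            )
        params = RateParameters(
            k_on=rates.k_on.value,
            k_off=0.0 if rates.irreversible else rates.k_off.value,
            k_cat=config.fixed.get("k_cat", 10.0),
            K_m=config.fixed.get("K_m", 200e-6),
        )
        noise_kwargs = {} if config.noise_sd is None else {"sd": config.noise_sd}
        noise = NoiseModel(seed=config.seed + index, **noise_kwargs)
        scheme = "irreversible" if rates.irreversible else "one_step"
        return generate_family(design, scheme, params, noise)
    return CurveFamily.read(name)


def run_kinetics(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Simulate/load every family, fit and discriminate schemes, and write
    per-family fit results plus a combined kinetic-constants report."""
    config.validate()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_json(config.to_dict(), out / "config.json")

    fixed = {"k_cat": config.fixed.get("k_cat", 10.0),
             "K_m": config.fixed.get("K_m", 200e-6)}
    summaries = []
    report: dict = {"families": {}}
    for i, name in enumerate(config.designs):
        t0 = time.perf_counter()
        family = _load_or_generate(config, name, i)
        fits, comparison, summary = analyze_family(
            family, config.schemes, fixed=fixed, inhibitor=config.inhibitor
        )
        summaries.append(summary)
        block = {
            "fits": {s.value: f.to_dict() for s, f in fits.items()},
            "comparison": comparison.to_dict(),
            "summary": summary.to_dict(),
        }
        report["families"][family.enzyme_name] = block
        _dump_json(block, out / f"fit_{family.enzyme_name}.json")
        logger.info("family %s analyzed in %.1f s", name, time.perf_counter() - t0)

    table = summary_table(summaries)
    table.to_csv(out / "kinetic_constants.csv")
    _dump_json(json.loads(table.to_json()), out / "kinetic_constants.json")
    report["table"] = json.loads(table.to_json())
    _dump_json(report, out / "report.json")
    return report


def fetch_structure(accession: str, directory: str | Path, fetch: bool = False) -> Path:
    """Resolve an accession to a local PDB path, optionally downloading it.

    Without ``fetch`` the file must already exist in *directory*; a missing
    file raises an actionable error instead of silently skipping.
    """
    directory = Path(directory)
    path = directory / f"{accession.upper()}.pdb"
    if path.exists():
        return path
    alt = directory / f"{accession.lower()}.pdb"
    if alt.exists():
        return alt
    if not fetch:
        raise FileNotFoundError(
            f"structure {accession} not found at {path}; download it there "
            f"or pass fetch=True / --fetch"
        )
    directory.mkdir(parents=True, exist_ok=True)
    url = RCSB_URL.format(accession=accession.upper())
    logger.info("fetching %s", url)
    with urllib.request.urlopen(url, timeout=60) as resp:
        path.write_bytes(resp.read())
    return path


def _run_one_job(job: dict, structure_dir: Path, fetch: bool) -> dict:
    """Execute one measurement job; returns a result row with provenance."""
    kind = job.get("measure")
    if kind is None:
        raise InvalidStateError(f"job missing 'measure': {job}")

    def model_for(key: str = "structure"):
        ref = job[key]
        path = Path(ref)
        if not path.exists():
            path = fetch_structure(ref, structure_dir, fetch)
        return read_structure(path), str(path)

    row = {"measure": kind}
    if kind == "distance":
        model, path = model_for()
        value = atom_distance(model, job["atom_a"], job["atom_b"])
        row.update(value=value, units="angstrom", file=path,
                   selectors=[job["atom_a"], job["atom_b"]])
    elif kind == "chi1":
        model, path = model_for()
        measure = chi1(model, job["residue"])
        row.update(value=measure.degrees, units="degrees", file=path,
                   selectors=[job["residue"]], resname=measure.resname)
    elif kind == "angles":
        model, path = model_for()
        angles, mean = angles_at_center(model, job["center"], job["substituents"])
        row.update(value=mean, units="degrees", file=path, angles=angles,
                   selectors=[job["center"]] + list(job["substituents"]))
    elif kind == "sasa":
        model, path = model_for()
        if "chain" in job:
            model = select_chain(model, job["chain"])
        result = sasa(model)
        row.update(value=result.total, units="angstrom^2", file=path,
                   selectors=[job.get("chain", "all")])
    elif kind == "buried_area":
        model, path = model_for()
        value = buried_area(model, job["part_a"], job["part_b"])
        row.update(value=value, units="angstrom^2", file=path,
                   selectors=[job["part_a"], job["part_b"]])
    elif kind == "superpose_rmsd":
        model1, path1 = model_for("structure")
        model2, path2 = model_for("structure_2")
        ca1 = ca_atoms(model1, job.get("chain"))
        ca2 = ca_atoms(model2, job.get("chain_2", job.get("chain")))
        from .interface_geometry import _pair_by_residue

        c1, c2 = _pair_by_residue(ca1, ca2)
        sup = superpose(c1, c2)
        row.update(value=sup.rmsd, units="angstrom", file=f"{path1},{path2}",
                   selectors=[job.get("chain", "*"), job.get("chain_2", "*")],
                   n_atoms=sup.n_atoms)
    elif kind == "docking_angle":
        model1, path1 = model_for("structure")
        model2, path2 = model_for("structure_2")
        value = docking_angle(
            model1, model2,
            (job["protease_chain"], job.get("protease_chain_2", job["protease_chain"])),
            (job["inhibitor_chain"], job.get("inhibitor_chain_2", job["inhibitor_chain"])),
        )
        row.update(value=value, units="degrees", file=f"{path1},{path2}",
                   selectors=[job["protease_chain"], job["inhibitor_chain"]])
    elif kind == "contacts":
        model, path = model_for()
        recs = contacts(
            select_chain(model, job["group_a"]),
            select_chain(model, job["group_b"]),
            ContactThresholds(),
        )
        row.update(value=len(recs), units="count", file=path,
                   selectors=[job["group_a"], job["group_b"]],
                   contacts=[
                       {
                           "a": f"{r.atom_a.chain}:{r.atom_a.resnum}:{r.atom_a.name}",
                           "b": f"{r.atom_b.chain}:{r.atom_b.resnum}:{r.atom_b.name}",
                           "distance": round(r.distance, 3),
                           "class": r.contact_class,
                       }
                       for r in recs
                   ])
    else:
        raise InvalidStateError(f"unknown measurement kind {kind!r}")
    return row


def run_geometry(
    config: RunConfig,
    output_dir: str | Path | None = None,
    structure_dir: str | Path = "structures",
    fetch: bool = False,
) -> pd.DataFrame:
    """Run every structure measurement job; one row per measurement.

    Duplicate jobs are deduplicated with a warning; missing files raise.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seen = set()
    rows = []
    for job in config.structure_jobs:
        key = json.dumps(job, sort_keys=True)
        if key in seen:
            logger.warning("duplicate measurement job skipped: %s", key)
            continue
        seen.add(key)
        rows.append(_run_one_job(job, Path(structure_dir), fetch))
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "geometry_measurements.csv", index=False)
    _dump_json(rows, out / "geometry_measurements.json")
    return frame
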