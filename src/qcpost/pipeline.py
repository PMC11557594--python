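"""End-to-end report pipeline: records in, CSV tables and spectra out.

`run_pipeline` wires the stages together the way the underlying study is
organised: a descriptor/gap/dipole table, a binding-energy site table,
DOS/PDOS spectra per record, and vibrational assignment / differencing /
ranking reports, plus a consistency report flagging every cell that
disagrees with a user-supplied reference table beyond tolerance.

Outputs are plain CSV with one header row.  Rounded values (default 3
decimals, printed-table convention) go to the main file; a ``*_full.csv``
sidecar keeps full precision.  Re-running with the same configuration and
inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import binding as _binding
from . import descriptors as _desc
from . import dos as _dos
from . import vibrational as _vib
from .records import RecordSet, load_record, load_record_set

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("qcpost")

STAGES = ("descriptors", "binding", "dos", "pdos", "vib")


class PipelineError(RuntimeError):
    """At least one pipeline stage failed."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML file mirrors these fields)."""

    records: Optional[str] = None  # record collection (JSON)
    stages: Sequence[str] = STAGES
    out_dir: str = "qcpost-out"
    precision: int = 3

    # descriptors
    ref_chi: float = 0.0
    ref_eta: float = 7.0
    dn_rule: str = "difference"
    reference_descriptors: Optional[str] = None  # CSV to check against
    reference_tol: float = 0.0015

    # binding: each entry {complex: path, fragments: [paths], site_tag: str}
    binding_sets: Sequence[dict] = field(default_factory=tuple)

    # dos / pdos
    fwhm: float = 0.3
    grid_step: float = 0.01
    fermi_mode: str = "midgap"

    # vibrational
    exp_bands: Optional[str] = None  # CSV
    model_bands: Sequence[str] = field(default_factory=tuple)  # CSVs
    diff_bands_a: Optional[str] = None
    diff_bands_b: Optional[str] = None
    tol_assign: float = 100.0
    tol_diff: float = 50.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            obj = yaml.safe_load(fh) or {}
        unknown = set(obj) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)


def _write_csv(df: pd.DataFrame, path: Path, precision: Optional[int]) -> None:
    if precision is None:
        df.to_csv(path, lineterminator="\n")
    else:
        df.to_csv(path, lineterminator="\n",
                  float_format=f"%.{precision}f")


def _stage_descriptors(cfg: RunConfig, records: RecordSet, out: Path) -> list[Path]:
    ref = _desc.ReferenceMetal(chi=cfg.ref_chi, eta=cfg.ref_eta, rule=cfg.dn_rule)
    full = _desc.descriptor_table(records, ref)
    rounded = _desc.rounded_descriptor_table(full, cfg.precision)
    # carry dipole magnitude over to the rounded table when available
    if "tdm" in full.columns:
        rounded["tdm"] = [
            _desc.round_to_printed(v, cfg.precision) if pd.notna(v) else v
            for v in full["tdm"]
        ]
    paths = []
    p_full = out / "descriptors_full.csv"
    _write_csv(full, p_full, None)
    paths.append(p_full)
    p_rounded = out / "descriptors.csv"
    _write_csv(rounded, p_rounded, cfg.precision)
    paths.append(p_rounded)
    if cfg.reference_descriptors:
        reference = pd.read_csv(cfg.reference_descriptors, index_col="label")
        report = _desc.compare_tables(rounded, reference, tol=cfg.reference_tol)
        p_rep = out / "consistency_report.csv"
        report.to_csv(p_rep, index=False, lineterminator="\n")
        paths.append(p_rep)
        n_bad = int(report["exceeds_tol"].sum()) if len(report) else 0
        log.info("consistency report: %d differing cells, %d beyond tol",
                 len(report), n_bad)
    return paths


def _stage_binding(cfg: RunConfig, out: Path) -> list[Path]:
    rows = []
    for entry in cfg.binding_sets:
        comp = load_record(entry["complex"])
        frags = [load_record(p) for p in entry["fragments"]]
        for r in (comp, *frags):
            if r.total_energy is None:
                raise ValueError(f"record {r.label!r} lacks total_energy")
        fs = _binding.FragmentSet(
            complex_label=comp.label,
            complex_te=comp.total_energy,
            fragments=tuple((f.label, f.total_energy) for f in frags),
            site_tag=str(entry.get("site_tag", "")),
        )
        res = _binding.binding_energy(fs)
        rows.append(
            {
                "label": res.label,
                "site_tag": res.site_tag,
                "TE_au": fs.complex_te,
                "BE_au": res.be_au,
                "BE_eV": res.be_ev,
            }
        )
    df = pd.DataFrame(rows).set_index("label")
    p = out / "binding.csv"
    _write_csv(df, p, cfg.precision)
    return [p]


def _stage_dos(cfg: RunConfig, records: RecordSet, out: Path,
               projected: bool) -> list[Path]:
    spec = _dos.BroadeningSpec(fwhm=cfg.fwhm, grid_step=cfg.grid_step)
    paths = []
    for rec in records:
        occ, virt = _dos.split_occupied_virtual(rec)
        if occ and virt:
            shift = -_dos.fermi_reference(max(occ), min(virt), cfg.fermi_mode)
        else:
            shift = 0.0
        if projected:
            if rec.population_weights is None:
                log.warning("record %r has no population weights; skipping PDOS",
                            rec.label)
                continue
            curves = _dos.pdos_curves(
                rec.orbital_energies, rec.population_weights,
                rec.group_names, spec, shift=shift,
            )
            curves.insert(
                0, _dos.dos_curve(rec.orbital_energies, spec, shift=shift)
            )
            name = f"pdos_{rec.label}.csv"
        else:
            curves = [_dos.dos_curve(rec.orbital_energies, spec, shift=shift)]
            name = f"dos_{rec.label}.csv"
        df = _dos.curves_to_frame(curves)
        p = out / name
        df.to_csv(p, index=False, lineterminator="\n", float_format="%.6g")
        paths.append(p)
    return paths


def _stage_vib(cfg: RunConfig, out: Path) -> list[Path]:
    paths = []
    exp = None
    if cfg.exp_bands:
        exp = _vib.bands_from_frame(pd.read_csv(cfg.exp_bands),
                                    source=Path(cfg.exp_bands).stem)
    if exp is not None and cfg.model_bands:
        scores = []
        rows = []
        for mp in cfg.model_bands:
            model = _vib.bands_from_frame(pd.read_csv(mp), source=Path(mp).stem)
            ar = _vib.assign_bands(model, exp, tol=cfg.tol_assign)
            for mb, eb, r in ar.pairs:
                rows.append({"model": model.source, "model_band": str(mb),
                             "exp_band": str(eb), "residual": r})
            scores.append(_vib.model_error(ar))
        pd.DataFrame(rows).to_csv(out / "assignments.csv", index=False,
                                  lineterminator="\n")
        ranked = _vib.rank_models(scores)
        pd.DataFrame(
            [{"model": s.model, "mad": s.mad, "rmsd": s.rmsd,
              "n_matched": s.n_matched} for s in ranked]
        ).to_csv(out / "model_ranking.csv", index=False, lineterminator="\n")
        paths += [out / "assignments.csv", out / "model_ranking.csv"]
    if cfg.diff_bands_a and cfg.diff_bands_b:
        a = _vib.bands_from_frame(pd.read_csv(cfg.diff_bands_a),
                                  source=Path(cfg.diff_bands_a).stem)
        b = _vib.bands_from_frame(pd.read_csv(cfg.diff_bands_b),
                                  source=Path(cfg.diff_bands_b).stem)
        d = _vib.diff_bands(a, b, tol=cfg.tol_diff)
        rows = (
            [{"kind": "new", "band": str(x), "shift": ""} for x in d.new]
            + [{"kind": "lost", "band": str(x), "shift": ""} for x in d.lost]
            + [{"kind": "shifted", "band": f"{ba} -> {bb}", "shift": s}
               for ba, bb, s in d.shifted]
        )
        pd.DataFrame(rows).to_csv(out / "band_diff.csv", index=False,
                                  lineterminator="\n")
        paths.append(out / "band_diff.csv")
    return paths


def run_pipeline(cfg: RunConfig) -> dict[str, list[Path]]:
    """Run the selected stages; returns {stage: [paths written]}.

    Per-stage failures are logged and collected; a :class:`PipelineError`
    listing the failed stages is raised at the end so one bad stage never
    silently suppresses the others.
    """
    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = None
    if cfg.records:
        records = load_record_set(cfg.records)
    written: dict[str, list[Path]] = {}
    failures: dict[str, str] = {}
    for stage in cfg.stages:
        try:
            if stage == "descriptors":
                if records is None:
                    raise ValueError("descriptors stage needs a records file")
                written[stage] = _stage_descriptors(cfg, records, out)
            elif stage == "binding":
                if not cfg.binding_sets:
                    log.info("no binding sets configured; skipping")
                    continue
                written[stage] = _stage_binding(cfg, out)
            elif stage in ("dos", "pdos"):
                if records is None:
                    raise ValueError(f"{stage} stage needs a records file")
                written[stage] = _stage_dos(cfg, records, out,
                                            projected=stage == "pdos")
            elif stage == "vib":
                written[stage] = _stage_vib(cfg, out)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            failures[stage] = str(exc)
    if failures:
        raise PipelineError(
            "; ".join(f"{k}: {v}" for k, v in failures.items())
        )
    return written
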