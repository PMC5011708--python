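"""Columnar text I/O for spectrum sets, parameter tables and reports.

Spectrum sets are stored as TSV with one block per detector group:
a ``# q=<value>`` line opens each block, followed by rows of
``energy_meV  intensity  sigma``.  The format is human-readable and
diff-able, which is what reduced QENS data usually looks like.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CellModelResults
from .spectra import EnergyGrid, QENSSpectrum, ResolutionModel, SpectrumSet

__all__ = [
    "read_spectrum_set",
    "write_spectrum_set",
    "resolve_resolution",
    "write_parameter_tables",
    "read_parameter_tables",
    "write_dispersion_csv",
]

# Table-1-style rounding for printed reports: decimals per parameter
_REPORT_DECIMALS = {
    "p_elastic": 2, "p_hyd": 2, "p_bulk": 2, "p_proteome": 2,
    "D_Tbulk": 7, "tau_bulk": 2, "D_Rbulk": 2,
    "D_Thyd": 9, "tau_hyd": 2, "D_Rhyd": 2, "Gamma_proteome": 3,
}


def resolve_resolution(spec) -> ResolutionModel:
    """Coerce a resolution specification into a ResolutionModel.

    Accepts a ResolutionModel, a positive number (Gaussian FWHM in
    meV), or a path to a two-column TSV (energy meV, density).
    """
    if isinstance(spec, ResolutionModel):
        return spec
    if isinstance(spec, (int, float)):
        return ResolutionModel.gaussian(float(spec))
    path = Path(spec)
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: resolution table must have two columns")
    return ResolutionModel.tabulated(arr[:, 0], arr[:, 1])


def write_spectrum_set(spectrum_set: SpectrumSet, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# qenscell spectrum set\n")
        if spectrum_set.label:
            fh.write(f"# label={spectrum_set.label}\n")
        fh.write("# columns: energy_meV\tintensity\tsigma\n")
        for s in spectrum_set.spectra:
            fh.write(f"# q={s.q:.6g}\n")
            for e, i, sg in zip(s.grid.energies, s.intensity, s.sigma):
                fh.write(f"{e:.9g}\t{i:.9g}\t{sg:.9g}\n")


def read_spectrum_set(path, resolution) -> SpectrumSet:
    """Parse a spectra TSV and attach the resolution.

    Malformed rows, non-positive sigmas and inconsistent energy grids
    across Q blocks are rejected with the offending line number.
    """
    path = Path(path)
    label = ""
    blocks: list[tuple[float, list[float], list[float], list[float]]] = []
    current = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("label="):
                    label = body[len("label="):]
                elif body.startswith("q="):
                    try:
                        q = float(body[2:])
                    except ValueError:
                        raise ValueError(f"{path}:{lineno}: bad q header {line!r}")
                    current = (q, [], [], [])
                    blocks.append(current)
                continue
            if current is None:
                raise ValueError(f"{path}:{lineno}: data before any '# q=' header")
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                e, i, sg = (float(p) for p in parts)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {line!r}")
            if sg <= 0:
                raise ValueError(f"{path}:{lineno}: sigma must be positive (got {sg})")
            if i < 0:
                raise ValueError(f"{path}:{lineno}: negative intensity (got {i})")
            current[1].append(e)
            current[2].append(i)
            current[3].append(sg)
    if not blocks:
        raise ValueError(f"{path}: no spectra found")
    grid0 = None
    spectra = []
    for q, e, i, sg in blocks:
        energies = np.array(e)
        if grid0 is None:
            grid0 = EnergyGrid(energies)
        elif not np.array_equal(energies, grid0.energies):
            raise ValueError(f"{path}: energy grid of q={q:g} block differs from first block")
        spectra.append(
            QENSSpectrum(q=q, grid=grid0, intensity=np.array(i), sigma=np.array(sg))
        )
    spectra.sort(key=lambda s: s.q)
    return SpectrumSet(
        spectra=tuple(spectra), resolution=resolve_resolution(resolution), label=label
    )


def write_parameter_tables(result: CellModelResults, outdir) -> tuple[Path, Path]:
    """Write params.csv / params_stderr.csv with Table-1-style columns."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = result.params.to_dict()
    names = list(result.REPORT_NAMES)
    values = pd.DataFrame(
        [{n: round(d[n], _REPORT_DECIMALS[n]) for n in names}
         | {"chi2_reduced": result.chi2_reduced}]
    )
    errs = pd.DataFrame(
        [{n: result.bse.get(n, np.nan) for n in names} | {"seed": result.seed}]
    )
    p1, p2 = outdir / "params.csv", outdir / "params_stderr.csv"
    values.to_csv(p1, index=False)
    errs.to_csv(p2, index=False)
    return p1, p2


def read_parameter_tables(outdir) -> tuple[pd.Series, pd.Series]:
    outdir = Path(outdir)
    values = pd.read_csv(outdir / "params.csv").iloc[0]
    errs = pd.read_csv(outdir / "params_stderr.csv").iloc[0]
    return values, errs


def write_dispersion_csv(curve, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"q2_A-2": curve.q2, "hwhm_meV": curve.hwhm, "hwhm_err_meV": curve.hwhm_err}
    ).to_csv(path, index=False)
    return path


def write_derived_json(result: CellModelResults, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(result.derived(), indent=2) + "\n")
    return path
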