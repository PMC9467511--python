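"""Serialization of parameterized spectrograms and benchmark reports.

Floats are rounded to 6 significant digits before writing and keys are
sorted, so two runs with identical configuration and seed produce
byte-identical JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .specfit import AperiodicParams, Peak, SpectralFit
from .spectral import Spectrogram
from .pipeline import ParameterizedSpectrogram

__all__ = ["write_parameterized", "read_parameterized", "write_report",
           "round_floats", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def round_floats(obj, sig: int = 6):
    """Recursively round floats to ``sig`` significant digits."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    return obj


def _fit_to_dict(fit: SpectralFit) -> dict:
    ap = {"mode": fit.aperiodic.mode, "offset": fit.aperiodic.offset,
          "exponent": fit.aperiodic.exponent}
    if fit.aperiodic.mode == "knee":
        ap["knee"] = fit.aperiodic.knee
    return {"time": fit.time, "aperiodic": ap,
            "peaks": [{"cf": p.cf, "amplitude": p.amplitude, "sd": p.sd}
                      for p in fit.peaks],
            "gof": {"mae": fit.mae, "r2": fit.r_squared},
            "status": list(fit.status)}


def _fit_from_dict(d: dict) -> SpectralFit:
    ap = d["aperiodic"]
    aperiodic = AperiodicParams(offset=ap["offset"], exponent=ap["exponent"],
                                knee=ap.get("knee"), mode=ap["mode"])
    peaks = tuple(Peak(cf=p["cf"], amplitude=p["amplitude"], sd=p["sd"])
                  for p in d["peaks"])
    return SpectralFit(aperiodic=aperiodic, peaks=peaks, mae=d["gof"]["mae"],
                       r_squared=d["gof"]["r2"], time=d["time"],
                       status=tuple(d.get("status", [])))


def write_parameterized(ps: ParameterizedSpectrogram, path,
                        format: str = "json") -> None:
    """Write a parameterized spectrogram as JSON (full round-trip) or long
    TSV (time, param, value, peak_index)."""
    path = Path(path)
    if format == "json":
        doc = {"schema_version": SCHEMA_VERSION, "software_version": __version__,
               "options": ps.options, "provenance": ps.provenance,
               "spectrogram": ps.spectrogram.to_dict(),
               "fits": [_fit_to_dict(f) for f in ps.fits]}
        path.write_text(json.dumps(round_floats(doc), sort_keys=True,
                                   indent=1) + "\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# schema_version={SCHEMA_VERSION}\n")
            fh.write("time\tparam\tvalue\tpeak_index\n")
            for f in ps.fits:
                rows = [("offset", f.aperiodic.offset, ""),
                        ("exponent", f.aperiodic.exponent, "")]
                if f.aperiodic.mode == "knee":
                    rows.append(("knee", f.aperiodic.knee, ""))
                rows += [("mae", f.mae, ""), ("r2", f.r_squared, "")]
                for j, p in enumerate(f.peaks):
                    rows += [("cf", p.cf, j), ("amplitude", p.amplitude, j),
                             ("sd", p.sd, j)]
                for name, val, pidx in rows:
                    fh.write(f"{f.time:.6g}\t{name}\t{val:.6g}\t{pidx}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_parameterized(path) -> ParameterizedSpectrogram:
    """Read back a JSON file written by :func:`write_parameterized`."""
    doc = json.loads(Path(path).read_text())
    spec = Spectrogram.from_dict(doc["spectrogram"])
    fits = tuple(_fit_from_dict(d) for d in doc["fits"])
    return ParameterizedSpectrogram(fits=fits, spectrogram=spec,
                                    options=doc.get("options", {}),
                                    provenance=doc.get("provenance", {}))


def write_report(report, path) -> None:
    """Write a benchmark report (or any dict-like) as sorted JSON."""
    doc = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    doc["software_version"] = __version__
    Path(path).write_text(json.dumps(round_floats(doc), sort_keys=True,
                                     indent=1) + "\n")
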