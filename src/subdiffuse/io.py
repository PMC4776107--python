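"""Plain-text file formats and deterministic fixture generation.

Reflectance profiles travel as whitespace-delimited tables with a commented
key=value header; the ``domain`` key (``q`` or ``rho``) and the ``units``
declaration are mandatory, and stochastic provenance (seed, photon count)
is echoed so every file is reproducible from its header.  Phase functions
use the two-column format of :mod:`subdiffuse.phase`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from subdiffuse.model import ReflectanceProfile

__all__ = ["read_profile", "write_profile", "generate_fixture"]

_REQUIRED_KEYS = ("domain", "units")


def write_profile(profile: ReflectanceProfile, path) -> None:
    """Write a reflectance profile as a commented-header text table."""
    path = Path(path)
    cols = {"abscissa": profile.abscissa}
    for name in ("saa", "snake", "diffuse", "ballistic", "total"):
        if name in profile.components:
            cols[name] = np.asarray(profile.components[name])
    if profile.stderr is not None:
        cols["stderr"] = np.asarray(profile.stderr)
    df = pd.DataFrame(cols)
    buf = _io.StringIO()
    meta = {"domain": profile.domain,
            "units": "cm^-1" if profile.domain == "q" else "cm"}
    if profile.q_c is not None:
        meta["q_c"] = repr(profile.q_c)
    if profile.delta_weight is not None:
        meta["delta_weight"] = repr(profile.delta_weight)
    for k, v in profile.meta.items():
        meta[str(k)] = repr(v) if isinstance(v, float) else str(v)
    for k, v in meta.items():
        buf.write(f"# {k}={v}\n")
    buf.write("# columns: " + " ".join(df.columns) + "\n")
    df.to_string(buf, index=False, header=False,
                 float_format=lambda v: f"{v:.10e}")
    buf.write("\n")
    path.write_text(buf.getvalue())


def read_profile(path) -> ReflectanceProfile:
    """Read a profile table written by :func:`write_profile`.

    Rejects files without a domain declaration, with a non-monotone
    abscissa, or with negative reflectance values.
    """
    path = Path(path)
    meta: dict = {}
    columns: list[str] | None = None
    body: list[str] = []
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            content = stripped.lstrip("#").strip()
            if content.startswith("columns:"):
                columns = content.split(":", 1)[1].split()
            elif "=" in content:
                k, v = content.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            body.append(stripped)
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise ValueError(f"{path}: missing required header '# {key}=...'")
    domain = meta.pop("domain")
    if domain not in ("q", "rho"):
        raise ValueError(f"{path}: domain must be 'q' or 'rho', got {domain!r}")
    if columns is None:
        raise ValueError(f"{path}: missing '# columns:' header")
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep=r"\s+",
                     names=columns, engine="python")
    if df.isnull().any().any():
        raise ValueError(f"{path}: malformed data rows")
    absc = df["abscissa"].to_numpy(dtype=float)
    if np.any(np.diff(absc) <= 0):
        raise ValueError(f"{path}: abscissa must be strictly increasing")
    comps = {}
    for name in df.columns:
        if name in ("abscissa", "stderr"):
            continue
        vals = df[name].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"{path}: negative values in component {name!r}")
        comps[name] = vals
    if "total" not in comps:
        raise ValueError(f"{path}: profile must contain a 'total' column")
    q_c = float(meta.pop("q_c")) if "q_c" in meta else None
    dw = float(meta.pop("delta_weight")) if "delta_weight" in meta else None
    meta.pop("units", None)
    stderr = (df["stderr"].to_numpy(dtype=float)
              if "stderr" in df.columns else None)
    return ReflectanceProfile(domain=domain, abscissa=absc, components=comps,
                              q_c=q_c, delta_weight=dw, stderr=stderr,
                              meta=meta)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixture(kind: str, params: dict, seed: int, out: Path) -> Path:
    """Write a deterministic test fixture; returns the output path.

    Kinds: ``gaussian-phase`` (synthesized SAA phase table),
    ``mie-phase`` (Mie phase table for a sphere suspension),
    ``forward-profile`` (model total-reflectance profile) and
    ``noisy-profile`` (the same with multiplicative log-normal noise, by
    default 1%).  Identical (kind, params, seed) give identical bytes.
    """
    from subdiffuse.phase import (SaaPhaseParams, synthesize_saa,
                                  write_phase_function, map_phase_function)
    from subdiffuse.mie import SphereSuspension, mie_phase_function, \
        mie_bulk_properties
    from subdiffuse.model import OpticalProperties, reflectance_total_q

    out = Path(out)
    params = dict(params)
    if kind == "gaussian-phase":
        p = synthesize_saa(SaaPhaseParams(params["p_b"], params["Theta"]),
                           int(params.get("n_theta", 2048)))
        write_phase_function(p, out)
    elif kind == "mie-phase":
        susp = SphereSuspension(
            diameter=params["diameter"],
            wavelength_vacuum=params.get("wavelength", 0.515),
            n_sphere=complex(params["n_sphere"]),
            n_medium=params["n_medium"],
            mu_s=params.get("mu_s", 1.0))
        write_phase_function(
            mie_phase_function(susp, int(params.get("n_theta", 2048))), out)
    elif kind in ("forward-profile", "noisy-profile"):
        saa = SaaPhaseParams(params["p_b"], params["Theta"])
        props = OpticalProperties(
            mu_s=params.get("mu_s", 1.0), mu_a=params.get("mu_a", 0.0),
            mu_b=params["mu_b"], saa=saa,
            g=params.get("g", saa.g_saa), psi_b=params.get("psi_b"))
        q = np.asarray(params.get(
            "q_grid", np.concatenate([np.linspace(0.05, 1, 20),
                                      np.linspace(1.2, 40, 60)])), dtype=float)
        prof = reflectance_total_q(q, props)
        if kind == "noisy-profile":
            rng = np.random.default_rng(seed)
            sigma = params.get("noise", 0.01)
            noisy = prof.total * np.exp(rng.normal(0.0, sigma, q.size))
            prof.components = {"total": noisy}
            prof.meta["noise"] = repr(sigma)
        prof.meta["seed"] = str(seed)
        write_profile(prof, out)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return out
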