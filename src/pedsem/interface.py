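"""Reporting and visualization: DOT path diagrams and fit reports."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .estimation import FittedModel
from .model import ModelSpec

__all__ = ["model_to_dot", "fit_report", "parse_report_tsv"]


def _dot_quote(name: str) -> str:
    return f'"{name}"'


def model_to_dot(spec: ModelSpec, layout: str = "hierarchical") -> str:
    """Classic path diagram as Graphviz DOT text.

    Latent variables are ellipses, observed variables boxes, covariates
    plain nodes.  Single-headed edges carry loadings and structural or
    covariate coefficients (fixed values printed as edge labels); each
    variance component of each variable is drawn as a double-headed
    self-loop labeled with the component letter.  Node ordering is
    deterministic.
    """
    out = io.StringIO()
    out.write("digraph model {\n")
    if layout == "circular":
        out.write("  layout=circo;\n")
    else:
        out.write("  rankdir=TB;\n")
    for v in spec.latent_vars:
        out.write(f"  {_dot_quote(v)} [shape=ellipse];\n")
    for v in spec.observed_vars:
        out.write(f"  {_dot_quote(v)} [shape=box];\n")
    for v in spec.covariate_vars:
        out.write(f"  {_dot_quote(v)} [shape=plaintext];\n")

    def edge(src, dst):
        fixed = spec.constraints.get(("coef", src, dst))
        label = f' [label="{fixed:g}"]' if fixed is not None else ""
        out.write(f"  {_dot_quote(src)} -> {_dot_quote(dst)}{label};\n")

    for (lat, obs) in spec.measurement_edges:
        edge(lat, obs)
    for (src, dst) in spec.structural_edges:
        edge(src, dst)
    for v in spec.latent_vars + spec.observed_vars:
        for c in spec.components_of(v):
            out.write(f"  {_dot_quote(v)} -> {_dot_quote(v)} "
                      f'[dir=both, label="{c}"];\n')
    out.write("}\n")
    return out.getvalue()


def fit_report(fm: FittedModel, format: str = "text") -> str:
    """Render a fitted model as plain text or machine-parsable TSV.

    The TSV variant has a leading ``section`` column with values ``meta``,
    ``parameter``, and ``fit``; :func:`parse_report_tsv` reads it back.
    """
    from . import __version__

    params = fm.parameter_table()
    fit_rows = fm.fit.as_rows() if fm.fit is not None else []
    cfi_val = fm.fit.cfi if fm.fit is not None else np.nan
    meta = [("version", __version__), ("seed", fm.seed),
            ("weight", fm.weight), ("Q_min", fm.Q_min), ("df", fm.df),
            ("converged", fm.converged), ("n_starts_used", fm.n_starts_used),
            ("cfi", cfi_val)]

    if format == "tsv":
        lines = ["section\tname\trole\testimate\tse\tz\tp\tfixed"]
        for key, val in meta:
            lines.append(f"meta\t{key}\t\t{val}\t\t\t\t")
        for _, r in params.iterrows():
            lines.append("parameter\t{name}\t{role}\t{estimate!r}\t{se!r}"
                         "\t{z!r}\t{p!r}\t{fixed}".format(**r))
        for (name, stat, df, p) in fit_rows:
            lines.append(f"fit\t{name}\t\t{stat!r}\t{df!r}\t\t{p!r}\t")
        return "\n".join(lines) + "\n"

    out = io.StringIO()
    out.write("Fitted pedigree SEM\n")
    for key, val in meta[:-1]:
        out.write(f"  {key}: {val}\n")
    out.write("\nParameters:\n")
    out.write(f"  {'name':28s} {'role':4s} {'estimate':>10s} {'se':>10s} "
              f"{'z':>8s} {'p':>10s}\n")
    for _, r in params.iterrows():
        if r["fixed"]:
            out.write(f"  {r['name']:28s} {r['role']:4s} "
                      f"{r['estimate']:10.4f}    (fixed)\n")
        else:
            out.write(f"  {r['name']:28s} {r['role']:4s} {r['estimate']:10.4f} "
                      f"{r['se']:10.4f} {r['z']:8.3f} {r['p']:10.4g}\n")
    if fit_rows:
        out.write("\nFit indices:\n")
        out.write(f"  {'index':24s} {'statistic':>10s} {'df':>7s} {'p':>10s}\n")
        for (name, stat, df, p) in fit_rows:
            out.write(f"  {name:24s} {stat:10.4f} {df:7.3g} {p:10.4g}\n")
        out.write(f"  CFI: {cfi_val:.4f}\n" if np.isfinite(cfi_val)
                  else "  CFI: NA\n")
    else:
        out.write("\nFit indices: NA (saturated model, df = 0)\n")
    return out.getvalue()


def parse_report_tsv(text: str):
    """Read a TSV fit report back into (meta dict, parameter frame, fit frame)."""
    frame = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    meta = {}
    for _, r in frame[frame["section"] == "meta"].iterrows():
        meta[r["name"]] = r["estimate"]
    pf = frame[frame["section"] == "parameter"].copy()
    for col in ("estimate", "se", "z", "p"):
        pf[col] = pd.to_numeric(pf[col], errors="coerce")
    pf["fixed"] = pf["fixed"].astype(str).str.lower() == "true"
    ff = frame[frame["section"] == "fit"].copy()
    ff = ff.rename(columns={"estimate": "statistic", "se": "df"})
    for col in ("statistic", "df", "p"):
        ff[col] = pd.to_numeric(ff[col], errors="coerce")
    return meta, pf.reset_index(drop=True), ff.reset_index(drop=True)
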