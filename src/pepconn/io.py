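"""Delimited-text readers and writers for the package's input tables.

Formats (CSV by default, TSV detected from the ``.tsv`` suffix):

* expression — wide table, one ``gene`` column then one column per neuron
  or per neuron class; values in {0, 1, true, false}. Class columns are
  broadcast to every member neuron of the roster.
* interactions — columns ``peptide_id, npp_gene, gpcr_gene, ec50``; EC50 in
  molar by default, or nanomolar with ``ec50_unit="nM"``.
* anatomy — columns ``neuron, bundles, region, strata`` with semicolon
  separated multi-valued fields.
* wired networks — edge lists with columns ``pre, post, weight``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    InteractionEntry,
    NeuronAnnotation,
    WiredNetwork,
)
from .roster import NeuronRoster

PHARYNX_BUNDLE = "pharynx"
NERVE_RING_BUNDLE = "nerve_ring"

_TRUTHY = {"1", "true", "True", "TRUE"}
_FALSY = {"0", "false", "False", "FALSE", ""}


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _class_members(name: str, roster: NeuronRoster) -> list[str]:
    """Neurons covered by a class-level column name.

    A column matches class ``c`` exactly, or the dorsal/ventral split
    sub-classes ``cD``/``cV`` (so ``CEP`` covers CEPD and CEPV members, and
    ``RMD`` covers RMD, RMDD and RMDV members, matching how class-level
    expression calls are reported).
    """
    members = []
    for n in roster.names:
        c = roster.class_of[n]
        if c == name or (c.startswith(name) and c[len(name):] in ("D", "V")):
            members.append(n)
    return members


def load_expression(
    path: str | Path, roster: NeuronRoster, threshold_level: int = 4
) -> ExpressionMatrix:
    """Read a binary gene x neuron (or gene x class) expression table.

    Class-level columns are broadcast to all member neurons. Unknown column
    names and non-binary values are hard errors.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str).fillna("0")
    if "gene" not in df.columns:
        raise ValueError(f"{path}: expected a 'gene' column")
    genes = df["gene"].tolist()
    idx = roster.index()
    n = len(roster)
    X = np.zeros((len(genes), n), dtype=bool)
    unknown = []
    for col in df.columns:
        if col == "gene":
            continue
        if col in idx:
            targets = [idx[col]]
        else:
            members = _class_members(col, roster)
            if not members:
                unknown.append(col)
                continue
            targets = [idx[m] for m in members]
        vals = df[col].astype(str).str.strip()
        bad = ~(vals.isin(_TRUTHY) | vals.isin(_FALSY))
        if bad.any():
            rows = list(df.index[bad][:5])
            raise ValueError(
                f"{path}: non-binary values in column {col!r} at rows {rows}"
            )
        b = vals.isin(_TRUTHY).to_numpy()
        for t in targets:
            X[:, t] |= b
    if unknown:
        raise ValueError(
            f"{path}: unknown neuron/class column(s): {sorted(unknown)}"
        )
    return ExpressionMatrix(
        genes=genes, roster=roster, X=X, threshold_level=threshold_level
    )


def save_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        expr.X.astype(int), index=pd.Index(expr.genes, name="gene"),
        columns=list(expr.roster.names),
    )
    df.to_csv(path, sep=_sep(path))


def load_interactions(
    path: str | Path, ec50_unit: str = "M"
) -> list[InteractionEntry]:
    """Read peptide-receptor interaction entries; EC50 stored in molar."""
    if ec50_unit not in ("M", "nM"):
        raise ValueError("ec50_unit must be 'M' or 'nM'")
    scale = 1.0 if ec50_unit == "M" else 1e-9
    # dtype=str so EC50 goes through python float(): correctly rounded parse
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"peptide_id", "npp_gene", "gpcr_gene", "ec50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        try:
            ec50 = float(row["ec50"]) * scale
        except (TypeError, ValueError):
            raise ValueError(f"{path}: unparsable EC50 at row {i}") from None
        if not ec50 > 0:
            raise ValueError(f"{path}: nonpositive EC50 at row {i}")
        entries.append(
            InteractionEntry(
                peptide_id=str(row["peptide_id"]),
                npp_gene=str(row["npp_gene"]),
                gpcr_gene=str(row["gpcr_gene"]),
                ec50=ec50,
            )
        )
    return entries


def save_interactions(
    entries: list[InteractionEntry], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "peptide_id": e.peptide_id,
                "npp_gene": e.npp_gene,
                "gpcr_gene": e.gpcr_gene,
                "ec50": e.ec50,
            }
            for e in entries
        ]
    ).to_csv(path, sep=_sep(path), index=False, float_format="%.17g")


def load_annotations(
    path: str | Path,
    roster: NeuronRoster,
    valid_bundles: list[str] | None = None,
) -> dict[str, NeuronAnnotation]:
    """Read per-neuron anatomy; every roster neuron must appear exactly once.

    ``in_pharynx`` is derived from membership in the ``pharynx`` bundle.
    When ``valid_bundles`` is given, unknown bundle names are an error that
    lists the accepted catalog.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str).fillna("")
    required = {"neuron", "bundles", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    seen = df["neuron"].tolist()
    extra = sorted(set(seen) - set(roster.names))
    if extra:
        raise ValueError(f"{path}: unknown neuron(s): {extra}")
    absent = sorted(set(roster.names) - set(seen))
    if absent:
        raise ValueError(f"{path}: missing neuron(s): {absent[:10]}...")
    valid = set(valid_bundles) if valid_bundles is not None else None
    out: dict[str, NeuronAnnotation] = {}
    for _, row in df.iterrows():
        bundles = frozenset(
            b.strip() for b in str(row["bundles"]).split(";") if b.strip()
        )
        if valid is not None and not bundles <= valid:
            raise ValueError(
                f"{path}: neuron {row['neuron']}: unknown bundle(s) "
                f"{sorted(bundles - valid)}; valid bundles are {sorted(valid)}"
            )
        strata_raw = str(row.get("strata", "") or "")
        strata = frozenset(
            int(s) for s in strata_raw.split(";") if s.strip()
        )
        out[row["neuron"]] = NeuronAnnotation(
            neuron=row["neuron"],
            bundles=bundles,
            region=str(row["region"]).strip(),
            strata=strata,
            in_pharynx=PHARYNX_BUNDLE in bundles,
        )
    return out


def save_annotations(
    ann: dict[str, NeuronAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "neuron": a.neuron,
            "bundles": ";".join(sorted(a.bundles)),
            "region": a.region,
            "strata": ";".join(str(s) for s in sorted(a.strata)),
        }
        for a in ann.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def load_wired(
    path: str | Path, name: str, roster: NeuronRoster
) -> WiredNetwork:
    """Assemble a wired connectome from a ``pre, post, weight`` edge list.

    Gap-junction networks are symmetrized with the elementwise maximum of
    the two directions; synaptic and monoamine networks stay directed.
    """
    df = pd.read_csv(path, sep=_sep(path))
    missing = {"pre", "post", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    idx = roster.index()
    unknown = sorted(
        set(df["pre"]).union(df["post"]) - set(roster.names)
    )
    if unknown:
        raise ValueError(f"{path}: neuron(s) not in roster: {unknown}")
    n = len(roster)
    A = np.zeros((n, n), dtype=int)
    for _, row in df.iterrows():
        A[idx[row["pre"]], idx[row["post"]]] += int(row["weight"])
    directed = name != "gap_junction"
    if not directed:
        A = np.maximum(A, A.T)
    return WiredNetwork(name=name, A=A, directed=directed, roster=roster)


def save_wired(net: WiredNetwork, path: str | Path) -> None:
    pre, post = np.nonzero(net.A)
    names = net.roster.names
    pd.DataFrame(
        {
            "pre": [names[i] for i in pre],
            "post": [names[j] for j in post],
            "weight": net.A[pre, post],
        }
    ).to_csv(path, sep=_sep(path), index=False)


def write_metadata(path: str | Path, **fields) -> None:
    """JSON sidecar recording provenance (thresholds, hashes, seeds)."""
    Path(path).write_text(json.dumps(fields, indent=2, sort_keys=True))
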