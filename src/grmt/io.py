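"""On-disk formats: mutation matrices (TSV), trees (DOT + parent vector,
Newick), attachments and JSON run reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import FREE, ROOT_PARENT, MutationMatrix, MutationTree, attached_nodes
from .likelihood import Attachment


def read_matrix(path, mode: str = "binary", missing_code: int = 3,
                transpose: bool = False) -> MutationMatrix:
    """Read a whitespace/tab-separated integer mutation matrix.

    Native orientation is cells in rows; pass ``transpose=True`` for
    mutations-in-rows dialects.  ``missing_code`` (default 3) and the symbol
    ``?`` both mark missing entries.  An optional first header row and first
    id column are detected when their fields are non-numeric.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append(line.split())
    if not rows:
        raise ValueError(f"{path}: empty matrix file")

    def _numeric(tok: str) -> bool:
        return tok == "?" or tok.lstrip("-").isdigit()

    header = None
    if not all(_numeric(t) for t in rows[0]):
        header = rows[0]
        rows = rows[1:]
    row_ids = None
    if rows and not _numeric(rows[0][0]):
        row_ids = [r[0] for r in rows]
        rows = [r[1:] for r in rows]
        if header is not None and len(header) == len(rows[0]) + 1:
            header = header[1:]

    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=np.int8)
    mask = np.zeros((len(rows), width), dtype=bool)
    hi = 1 if mode == "binary" else 2
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"{path}: ragged row {i + 1} "
                             f"({len(r)} fields, expected {width})")
        for j, tok in enumerate(r):
            if tok == "?":
                mask[i, j] = True
                data[i, j] = 0
                continue
            if not _numeric(tok):
                raise ValueError(f"{path}: illegal symbol {tok!r} at row {i + 1}")
            v = int(tok)
            if v == missing_code:
                mask[i, j] = True
                data[i, j] = 0
            elif 0 <= v <= hi:
                data[i, j] = v
            else:
                raise ValueError(
                    f"{path}: value {v} at row {i + 1} illegal for {mode} mode")
    if transpose:
        data, mask = data.T, mask.T
        cell_ids, mutation_ids = header, row_ids
    else:
        cell_ids, mutation_ids = row_ids, header
    return MutationMatrix(data=data, missing_mask=mask, mode=mode,
                          cell_ids=list(cell_ids or []),
                          mutation_ids=list(mutation_ids or []))


def write_matrix(mm: MutationMatrix, path, missing_code: int = 3) -> None:
    out = np.where(mm.missing_mask, missing_code, mm.data)
    with Path(path).open("w") as fh:
        for row in out:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def write_tree(tree: MutationTree, attachment: Attachment | None, path_prefix) -> tuple[Path, Path]:
    """Write a DOT rendering and a parent-vector sidecar.

    Returns ``(dot_path, parent_path)``.  Gain nodes carry the mutation id,
    loss nodes a ``-`` prefix; each node label shows its attached cell count
    when an attachment is given.
    """
    prefix = Path(path_prefix)
    dot_path = prefix.with_suffix(".dot")
    txt_path = prefix.with_suffix(".parent.txt")

    counts = np.zeros(tree.n_nodes, dtype=int)
    if attachment is not None:
        for x in np.asarray(attachment.xi):
            counts[int(x)] += 1
    with dot_path.open("w") as fh:
        fh.write("digraph mutation_tree {\n  node [shape=box];\n")
        for v in attached_nodes(tree):
            label = tree.node_label(v)
            if attachment is not None:
                label += f"\\n({counts[v]} cells)"
            fh.write(f'  n{v} [label="{label}"];\n')
        for v in attached_nodes(tree):
            if v != 0:
                fh.write(f"  n{int(tree.parent[v])} -> n{v};\n")
        fh.write("}\n")

    with txt_path.open("w") as fh:
        fh.write(f"# M={tree.M} k={tree.k}\n")
        fh.write(" ".join(str(int(p)) for p in tree.parent) + "\n")
        if attachment is not None:
            fh.write("# xi\n")
            fh.write(" ".join(str(int(x)) for x in attachment.xi) + "\n")
    return dot_path, txt_path


def read_parent_vector(path) -> tuple[MutationTree, np.ndarray | None]:
    """Re-parse a parent-vector sidecar written by ``write_tree``."""
    path = Path(path)
    M = k = None
    parent = None
    xi = None
    expect_xi = False
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "M=" in line and "k=" in line:
                    for tok in line[1:].split():
                        key, _, val = tok.partition("=")
                        if key == "M":
                            M = int(val)
                        elif key == "k":
                            k = int(val)
                expect_xi = "xi" in line
                continue
            vals = np.array([int(t) for t in line.split()], dtype=np.int32)
            if expect_xi:
                xi = vals
            else:
                parent = vals
    if M is None or k is None or parent is None:
        raise ValueError(f"{path}: not a parent-vector tree file")
    return MutationTree(M, k, parent), xi


def to_newick(tree: MutationTree) -> str:
    """Newick string of the attached-node topology (event labels as names)."""
    children: dict[int, list[int]] = {}
    for v in attached_nodes(tree):
        if v != 0:
            children.setdefault(int(tree.parent[v]), []).append(v)

    def rec(v: int) -> str:
        name = "root" if v == 0 else tree.node_label(v).replace("-", "loss_")
        kids = children.get(v, [])
        if not kids:
            return name
        return "(" + ",".join(rec(c) for c in sorted(kids)) + ")" + name

    return rec(0) + ";"


def run_report(result, path, seed: int | None = None,
               estimated: bool = False) -> dict:
    """Serialize a fit to JSON: likelihood, rates, hyper-parameters, trace."""
    from . import __version__

    params = result.params
    report = {
        "version": __version__,
        "loglik": result.best_loglik,
        "alpha": params.alpha if params else None,
        "beta": params.beta if params else None,
        "alpha_beta_estimated": bool(estimated),
        "k": params.k if params else None,
        "lambda": params.lam if params else None,
        "kappa": params.kappa if params else None,
        "seed": seed,
        "stop_reason": result.stop_reason,
        "n_attached": int(np.sum(result.best_tree.parent != FREE)),
        "trace": [
            {"t": r.t, "p": r.p, "c": r.c, "score": r.score, "loglik": r.loglik}
            for r in result.trace
        ],
    }
    with Path(path).open("w") as fh:
        json.dump(report, fh, indent=2)
    return report
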