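"""Point-cloud, result and table I/O.

PLY (ASCII) is the primary interchange format: it is the simplest standard
format carrying per-vertex integer scalars, here the property ``attribute``.
A minimal reader/writer is implemented in-package because the installed mesh
libraries do not round-trip custom integer vertex properties for point
clouds.  CSV files use the columns ``x,y,z,attribute`` (coordinates in mm).

Extra per-vertex scalar fields (e.g. force components, curl magnitude,
distance-map values) can be written alongside the coordinates for inspection
in external viewers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AttributedPointCloud
from .errors import MissingAttributeWarning, ParseError

__all__ = ["read_cloud", "write_cloud", "write_result", "write_table", "read_table",
           "RunConfig"]

_PLY_INT_TYPES = {"char", "uchar", "short", "ushort", "int", "uint",
                  "int8", "uint8", "int16", "uint16", "int32", "uint32"}
_PLY_FLOAT_TYPES = {"float", "double", "float32", "float64"}


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format='ply' or 'csv'")


def read_cloud(path, format: str | None = None) -> AttributedPointCloud:
    """Read an attributed point cloud from PLY (ASCII) or CSV.

    PLY files must provide float properties x, y, z on the vertex element; an
    integer property ``attribute`` is optional (absent: all attributes are
    zero, with a :class:`MissingAttributeWarning`).  CSV files need columns
    x, y, z and optionally attribute.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "ply":
        return _read_ply(path)
    raise ValueError(f"unsupported format {fmt!r}")


def _read_csv(path: Path) -> AttributedPointCloud:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if "attribute" in df.columns:
        attrs = df["attribute"].to_numpy()
    else:
        warnings.warn(f"{path}: no 'attribute' column; attributes set to 0",
                      MissingAttributeWarning, stacklevel=2)
        attrs = np.zeros(len(df), dtype=np.int64)
    return AttributedPointCloud(df[["x", "y", "z"]].to_numpy(float), attrs, name=path.stem)


def _read_ply(path: Path) -> AttributedPointCloud:
    with open(path, "r") as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ParseError(f"{path}: not a PLY file (first line {line!r})")
        fmt = fh.readline().strip()
        if not fmt.startswith("format ascii"):
            raise ParseError(f"{path}: only ASCII PLY is supported (got {fmt!r})")

        n_vertices = None
        properties: list[tuple[str, str]] = []
        in_vertex = False
        lineno = 2
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                raise ParseError(f"{path}: unexpected end of header")
            tokens = line.split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ParseError(f"{path}:{lineno}: list properties unsupported on vertices")
                properties.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if n_vertices is None:
            raise ParseError(f"{path}: no vertex element in header")

        names = [p[0] for p in properties]
        for req in ("x", "y", "z"):
            if req not in names:
                raise ParseError(f"{path}: vertex element lacks property {req!r}")
        try:
            data = np.loadtxt(fh, max_rows=n_vertices, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: bad vertex data: {exc}") from exc
        if data.shape != (n_vertices, len(properties)):
            raise ParseError(
                f"{path}: expected {n_vertices} x {len(properties)} vertex values, "
                f"got {data.shape}")

    cols = {name: data[:, i] for i, (name, _) in enumerate(properties)}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    if "attribute" in cols:
        attrs = cols["attribute"]
        ptype = dict(properties)["attribute"]
        if ptype not in _PLY_INT_TYPES:
            raise ParseError(f"{path}: property 'attribute' must be an integer type, got {ptype}")
    else:
        warnings.warn(f"{path}: no 'attribute' vertex property; attributes set to 0",
                      MissingAttributeWarning, stacklevel=2)
        attrs = np.zeros(len(points), dtype=np.int64)
    return AttributedPointCloud(points, attrs.astype(np.int64), name=path.stem)


def write_cloud(cloud: AttributedPointCloud, path, format: str | None = None,
                extra: dict | None = None) -> None:
    """Write a cloud to PLY (ASCII) or CSV; byte output is deterministic.

    ``extra`` maps field names to per-point scalar arrays (floats) written as
    additional vertex properties / columns (e.g. ``curl_magnitude``,
    ``distance``).
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    extra = extra or {}
    for key, arr in extra.items():
        if len(np.asarray(arr)) != len(cloud):
            raise ValueError(f"extra field {key!r} length mismatch")
    if fmt == "csv":
        df = pd.DataFrame({
            "x": cloud.points[:, 0],
            "y": cloud.points[:, 1],
            "z": cloud.points[:, 2],
            "attribute": cloud.attributes,
        })
        for key, arr in extra.items():
            df[key] = np.asarray(arr, float)
        df.to_csv(path, index=False, float_format="%.17g")
        return
    if fmt != "ply":
        raise ValueError(f"unsupported format {fmt!r}")

    lines = [
        "ply",
        "format ascii 1.0",
        f"comment {cloud.name or 'vfareg point cloud'}",
        f"element vertex {len(cloud)}",
        "property double x",
        "property double y",
        "property double z",
        "property int attribute",
    ]
    lines += [f"property double {key}" for key in extra]
    lines.append("end_header")
    cols = [np.char.mod("%.17g", cloud.points[:, i]) for i in range(3)]
    cols.append(cloud.attributes.astype(str))
    for arr in extra.values():
        cols.append(np.char.mod("%.17g", np.asarray(arr, float)))
    body = [" ".join(row) for row in zip(*cols)]
    path.write_text("\n".join(lines + body) + "\n")


def write_result(result, path, config=None) -> None:
    """Write a RegistrationResult (plus a config echo) as JSON."""
    payload = result.to_dict()
    if config is not None:
        from dataclasses import asdict, is_dataclass

        payload["config"] = asdict(config) if is_dataclass(config) else dict(config)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_table(rows, path) -> None:
    """Write a DataFrame (or records) as CSV with a fixed column order."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.9g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


class RunConfig:
    """Merged run configuration: generator, scan, registration, seeds, output.

    Serializes losslessly to JSON so every artifact can be reproduced from
    its config file; ``effective_hash`` is logged with outputs.
    """

    def __init__(self, phantom=None, scan=None, registration=None,
                 output_dir: str = ".", seed: int = 0):
        from .registration import RegistrationConfig
        from .synthetic import PhantomConfig, ScanConfig

        self.phantom = phantom or PhantomConfig(seed=seed)
        self.scan = scan or ScanConfig(seed=seed * 2 + 1)
        self.registration = registration or RegistrationConfig()
        self.output_dir = str(output_dir)
        self.seed = int(seed)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "phantom": asdict(self.phantom),
            "scan": asdict(self.scan),
            "registration": asdict(self.registration),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .registration import RegistrationConfig
        from .synthetic import PhantomConfig, ScanConfig

        def tupled(cfg: dict) -> dict:
            return {k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}

        return cls(
            phantom=PhantomConfig(**tupled(d.get("phantom", {}))),
            scan=ScanConfig(**tupled(d.get("scan", {}))),
            registration=RegistrationConfig(**d.get("registration", {})),
            output_dir=d.get("output_dir", "."),
            seed=d.get("seed", 0),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def effective_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
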