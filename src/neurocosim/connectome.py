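"""Connectome containers, readers/writers and a synthetic generator.

A connectome is a set of brain regions with a nonnegative directed weight
matrix and a tract-length matrix from which conduction delays are derived
(delay = length / conduction speed).  On disk, the package accepts either a
directory or a zip bundle containing ``weights`` and ``tract_lengths``
matrices (whitespace- or comma-separated) plus an optional ``centres`` file
with region labels (and coordinates), following the packaging convention of
whole-brain simulators.

The synthetic generator emulates the statistical shape of empirical
tractography connectomes (heavy-tailed log-normal weights, optional
mirrored hemispheric blocks, a designated seizure-seed region) without any
claim to anatomical accuracy.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Connectome:
    """Region labels, weights, tract lengths and derived delays."""

    labels: list[str]
    weights: np.ndarray        # (n, n) nonnegative, w[i, k] = strength k -> i
    tract_lengths: np.ndarray  # (n, n) mm
    conduction_speed: float = 3.0  # mm/ms
    proxy_region: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)
        n = len(self.labels)
        for name, m in (("weights", self.weights),
                        ("tract_lengths", self.tract_lengths)):
            if m.shape != (n, n):
                raise ValueError(
                    f"{name} must be {n}x{n} to match {n} labels, "
                    f"got {m.shape}")
        neg = np.argwhere(self.weights < 0)
        if neg.size:
            i, k = neg[0]
            raise ValueError(
                f"negative weight at row {i}, col {k}: "
                f"{self.weights[i, k]}")
        if np.any(self.tract_lengths < 0):
            raise ValueError("tract lengths must be nonnegative")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def delays(self) -> np.ndarray:
        """Conduction delays tau[i, k] = length[i, k] / speed (ms)."""
        return delays_from_lengths(self.tract_lengths, self.conduction_speed)

    def region_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"region label {label!r} not in connectome")


def delays_from_lengths(lengths: np.ndarray, speed: float) -> np.ndarray:
    """Elementwise conduction delay matrix (ms) from tract lengths (mm)."""
    if speed <= 0:
        raise ValueError("conduction speed must be positive")
    return np.asarray(lengths, dtype=float) / speed


def _parse_matrix(text: str) -> np.ndarray:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sep = "," if "," in line else None
        rows.append([float(x) for x in line.replace(",", " ").split()])
    if not rows:
        raise ValueError("empty matrix file")
    m = np.array(rows, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    return m


def _parse_centres(text: str) -> list[str]:
    labels = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "," in line:
            labels.append(line.split(",")[0].strip())
        else:
            # whitespace dialect: label may contain spaces, the last three
            # fields are coordinates
            parts = line.split()
            labels.append(" ".join(parts[:-3]) if len(parts) > 3
                          else parts[0])
    return labels


def read_connectome(path: str | Path, conduction_speed: float = 3.0,
                    proxy_region: str | int | None = None) -> Connectome:
    """Read a connectome from a directory or zip bundle.

    The bundle must contain ``weights`` and ``tract_lengths`` files (any
    extension; whitespace- or comma-separated square matrices) and may
    contain a ``centres`` file whose first column is the region label.
    Missing labels are auto-generated as ``region_0 .. region_{n-1}``.
    """
    path = Path(path)
    contents: dict[str, str] = {}
    if path.is_dir():
        for f in path.iterdir():
            contents[f.name] = f.read_text()
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as z:
            for name in z.namelist():
                base = Path(name).name
                if base:
                    contents[base] = z.read(name).decode()
    else:
        raise FileNotFoundError(f"{path} is neither a directory nor a zip")

    def find(stem: str) -> str | None:
        for name, text in contents.items():
            if Path(name).stem.lower() == stem:
                return text
        return None

    w_text = find("weights")
    l_text = find("tract_lengths")
    if w_text is None or l_text is None:
        raise FileNotFoundError(
            f"bundle {path} must contain 'weights' and 'tract_lengths' "
            f"files; found {sorted(contents)}")
    weights = _parse_matrix(w_text)
    lengths = _parse_matrix(l_text)
    if weights.shape != lengths.shape:
        raise ValueError(
            f"weights {weights.shape} and tract_lengths {lengths.shape} "
            f"differ in size")
    n = weights.shape[0]
    c_text = find("centres")
    if c_text is not None:
        labels = _parse_centres(c_text)
        if len(labels) != n:
            raise ValueError(
                f"centres file has {len(labels)} labels but matrices are "
                f"{n}x{n}")
    else:
        labels = [f"region_{i}" for i in range(n)]
    idx: int | None
    if isinstance(proxy_region, str):
        idx = labels.index(proxy_region)
    else:
        idx = proxy_region
    return Connectome(labels=labels, weights=weights, tract_lengths=lengths,
                      conduction_speed=conduction_speed, proxy_region=idx)


def write_connectome(conn: Connectome, path: str | Path,
                     as_zip: bool = False) -> Path:
    """Write weights/tract_lengths/centres as CSV text (dir or zip)."""
    path = Path(path)

    def mat_csv(m: np.ndarray) -> str:
        return "\n".join(",".join(f"{x:.12g}" for x in row) for row in m) \
            + "\n"

    centres = "".join(f"{lab},0.0,0.0,0.0\n" for lab in conn.labels)
    files = {
        "weights.txt": mat_csv(conn.weights),
        "tract_lengths.txt": mat_csv(conn.tract_lengths),
        "centres.txt": centres,
    }
    if as_zip:
        with zipfile.ZipFile(path, "w") as z:
            for name, text in files.items():
                z.writestr(name, text)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, text in files.items():
            (path / name).write_text(text)
    return path


@dataclass
class SyntheticConnectomeSpec:
    """Specification of a randomly generated surrogate connectome.

    Emulates heavy-tailed tractography weights (log-normal), uniformly
    distributed tract lengths and, optionally, the mirrored hemispheric
    block structure of bilateral atlases.  Weights are normalised to a
    maximum of 1 by default.
    """

    n_regions: int = 10
    density: float = 1.0
    weight_mu: float = -1.0        # log-normal location (of log weight)
    weight_sigma: float = 1.0      # log-normal scale
    length_range: tuple[float, float] = (3.0, 30.0)  # mm
    hemispheric_mirror: bool = False
    seed_region: str = "l CA1"
    seed_hub_scale: float = 3.0
    seed: int = 0
    normalise: bool = True

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.length_range[0] <= 0:
            raise ValueError("tract lengths must be positive")


def generate_synthetic(spec: SyntheticConnectomeSpec,
                       conduction_speed: float = 3.0) -> Connectome:
    """Generate a deterministic synthetic connectome from ``spec``.

    With ``hemispheric_mirror`` the regions split into two equal halves
    ("l ..."/"r ...") whose intra-hemisphere blocks are exact mirror
    copies, emulating the symmetric inter-hemispheric structure of
    bilateral atlas connectomes.  The designated seed region is always
    label index 0 of the left block.
    """
    n = spec.n_regions
    rng = np.random.default_rng(spec.seed)
    if spec.hemispheric_mirror and n % 2:
        raise ValueError("hemispheric_mirror requires an even region count")

    def sample_block(size):
        w = rng.lognormal(spec.weight_mu, spec.weight_sigma, (size, size))
        mask = rng.random((size, size)) < spec.density
        w *= mask
        np.fill_diagonal(w, 0.0)
        return w

    lengths = rng.uniform(*spec.length_range, (n, n))
    lengths = 0.5 * (lengths + lengths.T)
    np.fill_diagonal(lengths, 0.0)

    if spec.hemispheric_mirror:
        h = n // 2
        intra = sample_block(h)
        inter = rng.lognormal(spec.weight_mu - 1.0, spec.weight_sigma,
                              (h, h))
        inter *= rng.random((h, h)) < spec.density
        weights = np.block([[intra, inter], [inter.T, intra]])
        base = [spec.seed_region.split(" ", 1)[-1]] + \
            [f"r{i}" for i in range(1, h)]
        labels = [f"l {b}" for b in base] + [f"r {b}" for b in base]
        labels[0] = spec.seed_region
    else:
        weights = sample_block(n)
        labels = [spec.seed_region] + [f"region_{i}" for i in range(1, n)]
    if not np.any(weights > 0):
        raise ValueError(
            f"density {spec.density} produced an empty connectome at "
            f"n={n}; increase density or region count")
    if spec.normalise:
        weights = weights / weights.max()
    # the designated seed region is a hub: its outgoing projections are
    # strengthened, emulating a region prone to generating widespread
    # seizures
    weights[:, 0] *= spec.seed_hub_scale
    return Connectome(labels=labels, weights=weights, tract_lengths=lengths,
                      conduction_speed=conduction_speed, proxy_region=0)
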