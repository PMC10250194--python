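"""File formats and core containers for flexible-refinement workflows.

Volumes and image stacks are exchanged as MRC/MRCS (mode 2, float32).
Particle metadata is accepted either as a RELION-3.1-style STAR file or as a
flat CSV carrying the identical column names; CSV is written by default.

Conventions (declared, used consistently everywhere in the package):

* Euler angles ``(rot, tilt, psi)`` are in degrees, ZYZ, matching the RELION
  convention ``R = Rz(psi) @ Ry(tilt) @ Rz(rot)``.  The matrix maps
  canonical-frame coordinates to the microscope frame.
* Grids are 0-indexed; the rotation/projection origin is the voxel at index
  ``N // 2`` on each axis.  Volume arrays are indexed ``[z, y, x]`` and images
  ``[y, x]`` (row-major, first index increasing along +y), which matches the
  MRC section ordering.
* Shifts are in Angstrom (``rlnOriginXAngst`` / ``rlnOriginYAngst``).
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CanonicalVolume",
    "MaskVolume",
    "ParticleSet",
    "read_volume",
    "write_volume",
    "read_image_stack",
    "write_image_stack",
    "read_particles",
    "write_particles",
    "read_latents_csv",
    "write_latents_csv",
    "euler_to_matrix",
    "matrix_to_euler",
    "fourier_crop",
    "fourier_pad",
    "make_soft_mask",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CanonicalVolume:
    """A cubic real-space density grid with physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (N, N, N)
        Density values, arbitrary units, indexed ``[z, y, x]``.
    voxel_size : float
        Angstrom per voxel, > 0.
    bandlimit_radius : int or None
        Current Fourier-shell band-limit (cycles per box, 0..N/2), or None
        for unlimited.
    """

    data: np.ndarray
    voxel_size: float
    bandlimit_radius: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic, got non-cubic shape {self.data.shape}")
        n = self.data.shape[0]
        if n % 2 != 0 or n < 8:
            raise ValueError(f"box size must be even and >= 8, got {n}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if not (np.isfinite(self.voxel_size) and self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "CanonicalVolume":
        return CanonicalVolume(self.data.copy(), self.voxel_size, self.bandlimit_radius)


@dataclass
class MaskVolume:
    """A [0, 1]-valued volume used for solvent exclusion or motion freezing."""

    data: np.ndarray
    role: str = "solvent_exclusion"  # or "zero_deformation"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise ValueError("mask values must lie in [0, 1]")
        self.data = np.clip(self.data, 0.0, 1.0)


_CTF_COLUMNS = [
    "defocus_u_A",
    "defocus_v_A",
    "astig_angle_deg",
    "voltage_kV",
    "cs_mm",
    "amplitude_contrast",
    "phase_shift_rad",
]


@dataclass
class ParticleSet:
    """Particle images with per-particle pose, CTF, half-set and latents.

    ``rotations`` map canonical-frame coordinates into the microscope frame;
    ``shifts_A`` are 2D image translations in Angstrom.  ``ctf`` is a
    DataFrame with columns ``defocus_u_A, defocus_v_A, astig_angle_deg,
    voltage_kV, cs_mm, amplitude_contrast, phase_shift_rad``.
    """

    images: np.ndarray  # (M, N, N)
    rotations: np.ndarray  # (M, 3, 3)
    shifts_A: np.ndarray  # (M, 2), (x, y)
    ctf: pd.DataFrame
    pixel_size: float
    half_set: np.ndarray | None = None  # (M,) of "A"/"B"
    latents: np.ndarray | None = None  # (M, K)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.rotations = np.asarray(self.rotations, dtype=np.float64)
        self.shifts_A = np.asarray(self.shifts_A, dtype=np.float64)
        m = self.images.shape[0]
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError(f"images must be (M, N, N), got {self.images.shape}")
        for name, arr, lead in [
            ("rotations", self.rotations, (m, 3, 3)),
            ("shifts_A", self.shifts_A, (m, 2)),
        ]:
            if arr.shape != lead:
                raise ValueError(f"{name} must have shape {lead}, got {arr.shape}")
        if len(self.ctf) != m:
            raise ValueError(f"ctf table has {len(self.ctf)} rows for {m} particles")
        missing = [c for c in _CTF_COLUMNS if c not in self.ctf.columns]
        if missing:
            raise ValueError(f"ctf table missing columns {missing}")
        if not np.all(np.isfinite(self.ctf["defocus_u_A"])) or not np.all(
            np.isfinite(self.ctf["defocus_v_A"])
        ):
            raise ValueError("non-finite defocus in metadata")
        if np.any(self.ctf["defocus_u_A"] <= 0) or np.any(self.ctf["defocus_v_A"] <= 0):
            raise ValueError("defoci must be positive")
        err = np.max(
            np.abs(self.rotations @ np.transpose(self.rotations, (0, 2, 1)) - np.eye(3))
        )
        if err > 1e-6:
            raise ValueError(f"rotation matrices not orthonormal (max deviation {err:.2e})")
        if self.half_set is None:
            self.half_set = np.where(np.arange(m) % 2 == 0, "A", "B")
        self.half_set = np.asarray(self.half_set)
        if self.latents is not None:
            self.latents = np.asarray(self.latents, dtype=np.float64)
            if self.latents.shape[0] != m:
                raise ValueError("latents length mismatch")

    @property
    def m(self) -> int:
        return self.images.shape[0]

    @property
    def n(self) -> int:
        return self.images.shape[1]

    def subset(self, index: np.ndarray) -> "ParticleSet":
        index = np.asarray(index)
        return ParticleSet(
            images=self.images[index],
            rotations=self.rotations[index],
            shifts_A=self.shifts_A[index],
            ctf=self.ctf.iloc[index].reset_index(drop=True),
            pixel_size=self.pixel_size,
            half_set=self.half_set[index],
            latents=None if self.latents is None else self.latents[index],
        )

    def half(self, label: str) -> "ParticleSet":
        return self.subset(np.nonzero(self.half_set == label)[0])


# ---------------------------------------------------------------------------
# Euler angles

def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """RELION-convention ZYZ Euler triple (degrees) to rotation matrix."""
    r, t, p = np.deg2rad([rot, tilt, psi])
    return _rz(p) @ _ry(t) @ _rz(r)


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; returns degrees, tilt in [0, 180]."""
    tilt = np.arccos(np.clip(R[2, 2], -1.0, 1.0))
    if np.sin(tilt) > 1e-8:
        rot = np.arctan2(R[2, 1], -R[2, 0])
        psi = np.arctan2(R[1, 2], R[0, 2])
    else:  # degenerate: only rot+psi (or rot-psi) determined; put it all in psi
        rot = 0.0
        psi = np.arctan2(R[1, 0], R[0, 0]) if R[2, 2] > 0 else np.arctan2(-R[1, 0], -R[0, 0])
        if R[2, 2] < 0:
            psi = -psi
    return float(np.rad2deg(rot)), float(np.rad2deg(tilt)), float(np.rad2deg(psi))


# ---------------------------------------------------------------------------
# MRC mode-2 read/write
#
# Minimal implementation of the MRC2014 format restricted to mode 2
# (float32), which is all that cryo-EM volumes, masks and particle stacks
# need here.  Data are stored [section, row, column] = [z, y, x].

_MRC_HEADER_SIZE = 1024


def _read_mrc(path) -> tuple[np.ndarray, float]:
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_SIZE:
        raise ValueError(f"{path}: truncated MRC header")
    ints = np.frombuffer(raw[:_MRC_HEADER_SIZE], dtype="<i4")
    floats = np.frombuffer(raw[:_MRC_HEADER_SIZE], dtype="<f4")
    nx, ny, nz, mode = int(ints[0]), int(ints[1]), int(ints[2]), int(ints[3])
    if mode != 2:
        raise ValueError(f"{path}: only MRC mode 2 (float32) is supported, got mode {mode}")
    mapc, mapr, maps = int(ints[16]), int(ints[17]), int(ints[18])
    if (mapc, mapr, maps) != (1, 2, 3):
        raise ValueError(f"{path}: unsupported axis order {(mapc, mapr, maps)}")
    mx = int(ints[7])
    cella_x = float(floats[10])
    voxel = cella_x / mx if mx > 0 and cella_x > 0 else 0.0
    nsymbt = int(ints[23])
    count = nx * ny * nz
    data = np.frombuffer(
        raw, dtype="<f4", count=count, offset=_MRC_HEADER_SIZE + nsymbt
    ).reshape(nz, ny, nx)
    return data.astype(np.float32), voxel


def _write_mrc(path, data: np.ndarray, voxel_size: float, is_stack: bool = False) -> None:
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    header_i = np.zeros(256, dtype="<i4")
    header_f = header_i.view("<f4")
    header_i[0:3] = (nx, ny, nz)
    header_i[3] = 2  # mode
    # for an image stack mz counts one section per image; cella_z follows
    mz = 1 if is_stack else nz
    header_i[7:10] = (nx, ny, mz)
    header_f[10:13] = (nx * voxel_size, ny * voxel_size, mz * voxel_size)
    header_f[13:16] = (90.0, 90.0, 90.0)
    header_i[16:19] = (1, 2, 3)
    header_f[19] = float(data.min()) if data.size else 0.0
    header_f[20] = float(data.max()) if data.size else 0.0
    header_f[21] = float(data.mean()) if data.size else 0.0
    header_i[22] = 0 if is_stack else 1  # ispg: 0 = stack, 1 = volume
    header_i[27] = 20140  # nversion
    header_i[52] = struct.unpack("<i", b"MAP ")[0]
    header_i[53] = struct.unpack("<i", bytes([0x44, 0x44, 0x00, 0x00]))[0]
    header_f[54] = float(data.std()) if data.size else 0.0
    buf = io.BytesIO()
    buf.write(header_i.tobytes())
    buf.write(data.tobytes())
    Path(path).write_bytes(buf.getvalue())


def read_volume(path) -> CanonicalVolume:
    """Read a cubic MRC mode-2 volume; voxel size must be present."""
    data, voxel = _read_mrc(path)
    if len(set(data.shape)) != 1:
        raise ValueError(f"{path}: non-cubic volume of shape {data.shape}")
    if voxel <= 0:
        raise ValueError(f"{path}: missing voxel size in MRC header")
    return CanonicalVolume(data.astype(np.float64), voxel)


def write_volume(volume: CanonicalVolume, path) -> None:
    _write_mrc(path, volume.data, volume.voxel_size, is_stack=False)


def read_mask(path, role: str = "solvent_exclusion") -> MaskVolume:
    data, _ = _read_mrc(path)
    return MaskVolume(data.astype(np.float64), role=role)


def read_image_stack(path) -> tuple[np.ndarray, float]:
    """Read an MRCS particle stack; returns ``(images (M, N, N), pixel_size)``."""
    data, voxel = _read_mrc(path)
    return data, voxel


def write_image_stack(path, images: np.ndarray, pixel_size: float) -> None:
    _write_mrc(path, images, pixel_size, is_stack=True)


# ---------------------------------------------------------------------------
# particle metadata (STAR / CSV)

_RELION_MAP = {
    "rlnDefocusU": "defocus_u_A",
    "rlnDefocusV": "defocus_v_A",
    "rlnDefocusAngle": "astig_angle_deg",
    "rlnVoltage": "voltage_kV",
    "rlnSphericalAberration": "cs_mm",
    "rlnAmplitudeContrast": "amplitude_contrast",
}

_REQUIRED = [
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
    "rlnOriginXAngst",
    "rlnOriginYAngst",
    "rlnDefocusU",
    "rlnDefocusV",
    "rlnVoltage",
    "rlnSphericalAberration",
    "rlnAmplitudeContrast",
]


def _parse_star(path) -> pd.DataFrame:
    """Parse the first loop_ block of a STAR file into a DataFrame."""
    names: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                continue
            if line == "loop_":
                if rows:  # only the first loop block is read
                    break
                in_loop = True
                names = []
                continue
            if in_loop and line.startswith("_"):
                names.append(line.split()[0].lstrip("_"))
                continue
            if in_loop:
                fields = line.split()
                if len(fields) != len(names):
                    raise ValueError(
                        f"{path}: row has {len(fields)} fields for {len(names)} columns"
                    )
                rows.append(fields)
    if not names or not rows:
        raise ValueError(f"{path}: no loop_ data block found")
    df = pd.DataFrame(rows, columns=names)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".star":
        return _parse_star(path)
    return pd.read_csv(path)


def read_particles(stack_path, metadata_path) -> ParticleSet:
    """Read an MRCS stack plus STAR/CSV metadata into a :class:`ParticleSet`.

    Half-set labels are read from ``rlnRandomSubset`` (1 -> A, 2 -> B) when
    present, else assigned alternating by row index.  ``rlnPhaseShift`` is in
    degrees per the RELION convention and converted to radians.
    """
    images, pixel = read_image_stack(stack_path)
    meta = read_metadata(metadata_path)
    if len(meta) != images.shape[0]:
        raise ValueError(
            f"metadata has {len(meta)} rows but stack has {images.shape[0]} frames"
        )
    missing = [c for c in _REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns {missing}")
    rots = np.stack(
        [
            euler_to_matrix(r, t, p)
            for r, t, p in zip(meta["rlnAngleRot"], meta["rlnAngleTilt"], meta["rlnAnglePsi"])
        ]
    )
    shifts = np.column_stack([meta["rlnOriginXAngst"], meta["rlnOriginYAngst"]])
    ctf = pd.DataFrame({ours: meta[rln].to_numpy(float) for rln, ours in _RELION_MAP.items()})
    ctf["astig_angle_deg"] = (
        meta["rlnDefocusAngle"].to_numpy(float) if "rlnDefocusAngle" in meta else 0.0
    )
    ctf["phase_shift_rad"] = (
        np.deg2rad(meta["rlnPhaseShift"].to_numpy(float)) if "rlnPhaseShift" in meta else 0.0
    )
    half = None
    if "rlnRandomSubset" in meta:
        half = np.where(meta["rlnRandomSubset"].to_numpy(int) == 1, "A", "B")
    if pixel <= 0:
        pixel = float(meta["rlnImagePixelSize"].iloc[0]) if "rlnImagePixelSize" in meta else 1.0
    return ParticleSet(
        images=images.astype(np.float64),
        rotations=rots,
        shifts_A=shifts,
        ctf=ctf[_CTF_COLUMNS],
        pixel_size=pixel,
        half_set=half,
    )


def write_particles(particles: ParticleSet, stack_path, metadata_path) -> None:
    """Write the stack as MRCS and metadata as CSV with RELION column names."""
    write_image_stack(stack_path, particles.images.astype(np.float32), particles.pixel_size)
    eulers = np.array([matrix_to_euler(R) for R in particles.rotations])
    meta = pd.DataFrame(
        {
            "rlnAngleRot": eulers[:, 0],
            "rlnAngleTilt": eulers[:, 1],
            "rlnAnglePsi": eulers[:, 2],
            "rlnOriginXAngst": particles.shifts_A[:, 0],
            "rlnOriginYAngst": particles.shifts_A[:, 1],
            "rlnDefocusU": particles.ctf["defocus_u_A"],
            "rlnDefocusV": particles.ctf["defocus_v_A"],
            "rlnDefocusAngle": particles.ctf["astig_angle_deg"],
            "rlnVoltage": particles.ctf["voltage_kV"],
            "rlnSphericalAberration": particles.ctf["cs_mm"],
            "rlnAmplitudeContrast": particles.ctf["amplitude_contrast"],
            "rlnPhaseShift": np.rad2deg(particles.ctf["phase_shift_rad"]),
            "rlnRandomSubset": np.where(particles.half_set == "A", 1, 2),
            "rlnImagePixelSize": particles.pixel_size,
        }
    )
    meta.to_csv(metadata_path, index=False)


def read_latents_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = sorted([c for c in df.columns if c.startswith("z_")], key=lambda c: int(c[2:]))
    if not cols:
        raise ValueError(f"{path}: no z_k columns found")
    return df[cols].to_numpy(float)


def write_latents_csv(path, latents: np.ndarray) -> None:
    latents = np.atleast_2d(latents)
    df = pd.DataFrame(latents, columns=[f"z_{k + 1}" for k in range(latents.shape[1])])
    df.insert(0, "particle_index", np.arange(latents.shape[0]))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fourier cropping / padding

def _fourier_resize(data: np.ndarray, new_n: int) -> np.ndarray:
    n = data.shape[0]
    d = data.ndim
    if new_n % 2 != 0:
        raise ValueError(f"new box size must be even, got {new_n}")
    if new_n == n:
        return data.copy()
    spec = np.fft.fftshift(np.fft.fftn(data))
    if new_n < n:
        lo = n // 2 - new_n // 2
        sl = tuple(slice(lo, lo + new_n) for _ in range(d))
        out_spec = spec[sl]
    else:
        out_spec = np.zeros((new_n,) * d, dtype=complex)
        lo = new_n // 2 - n // 2
        sl = tuple(slice(lo, lo + n) for _ in range(d))
        out_spec[sl] = spec
    out = np.fft.ifftn(np.fft.ifftshift(out_spec)).real
    # scale so the real-space mean (DC / new_n^d) is preserved
    return out * (new_n / n) ** d


def fourier_crop(obj, new_n: int):
    """Centered Fourier crop of a volume or image to box size ``new_n``.

    The real-space mean is preserved and the voxel/pixel size rescales by
    ``N / new_n``.  Accepts a :class:`CanonicalVolume` or a bare 2D/3D array
    (bare arrays are returned as arrays).
    """
    if isinstance(obj, CanonicalVolume):
        n = obj.n
        if new_n > n:
            raise ValueError(f"cannot crop {n} to larger box {new_n}")
        return CanonicalVolume(
            _fourier_resize(obj.data, new_n), obj.voxel_size * n / new_n, obj.bandlimit_radius
        )
    data = np.asarray(obj, dtype=np.float64)
    if new_n > data.shape[0]:
        raise ValueError(f"cannot crop {data.shape[0]} to larger box {new_n}")
    return _fourier_resize(data, new_n)


def fourier_pad(obj, new_n: int):
    """Centered Fourier zero-pad (upsample) to box size ``new_n``."""
    if isinstance(obj, CanonicalVolume):
        n = obj.n
        if new_n < n:
            raise ValueError(f"cannot pad {n} to smaller box {new_n}")
        return CanonicalVolume(
            _fourier_resize(obj.data, new_n), obj.voxel_size * n / new_n, obj.bandlimit_radius
        )
    data = np.asarray(obj, dtype=np.float64)
    if new_n < data.shape[0]:
        raise ValueError(f"cannot pad {data.shape[0]} to smaller box {new_n}")
    return _fourier_resize(data, new_n)


# ---------------------------------------------------------------------------
# soft masks

def make_soft_mask(
    volume: CanonicalVolume,
    threshold: float,
    dilation_vox: float = 0.0,
    soft_edge_vox: float = 0.0,
) -> MaskVolume:
    """Binary threshold mask, Euclidean-dilated, with a cosine soft edge.

    The support after dilation is every voxel whose Euclidean distance (on
    voxel centers) to a voxel above threshold is <= ``dilation_vox``; the
    mask then falls from 1 to 0 over ``soft_edge_vox`` further voxels as
    ``0.5 (1 + cos(pi d / soft_edge))``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if dilation_vox < 0 or soft_edge_vox < 0:
        raise ValueError("dilation and soft edge must be >= 0")
    binary = volume.data > threshold
    if not binary.any():
        raise ValueError(f"empty mask: no voxel above threshold {threshold}")
    dist = ndimage.distance_transform_edt(~binary)
    mask = np.zeros(volume.data.shape)
    mask[dist <= dilation_vox] = 1.0
    if soft_edge_vox > 0:
        edge = (dist > dilation_vox) & (dist <= dilation_vox + soft_edge_vox)
        mask[edge] = 0.5 * (1.0 + np.cos(np.pi * (dist[edge] - dilation_vox) / soft_edge_vox))
    return MaskVolume(mask)
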