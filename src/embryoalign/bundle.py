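"""Per-embryo movie bundle: nuclei table + per-timepoint channel masks.

On disk a bundle is a directory::

    bundle/
      config.yaml            # grid, twitch time, embryo id, timepoint lists
      nuclei.csv             # t,x_um,y_um,z_um,intensity
      fiducial_gfp/t021.tiff (+ .yaml sidecars)
      reporter_gfp/t021.tiff ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import PipelineError
from .io import (
    AcquisitionGrid,
    LabelVolume,
    NucleiTimeSeries,
    read_label_volume,
    read_nuclei_table,
    write_label_volume,
    write_nuclei_table,
)


@dataclass
class EmbryoBundle:
    embryo_id: str
    grid: AcquisitionGrid
    nuclei: NucleiTimeSeries
    fiducial: dict[int, LabelVolume] = field(default_factory=dict)
    reporter: dict[int, LabelVolume] = field(default_factory=dict)
    twitch_time_min: float | None = None
    metadata: dict = field(default_factory=dict)

    def fiducial_at(self, t: int) -> LabelVolume:
        if t not in self.fiducial:
            raise PipelineError(f"{self.embryo_id}: no fiducial mask for timepoint {t}")
        return self.fiducial[t]

    def require_fiducial(self, timepoints: list[int]) -> None:
        missing = [t for t in timepoints if t not in self.fiducial]
        if missing:
            raise PipelineError(
                f"{self.embryo_id}: missing fiducial masks for timepoints {missing}"
            )

    @property
    def last_pretwitch_index(self) -> int:
        """Last fast timepoint strictly before twitching (last stored if unknown)."""
        stored = sorted(self.fiducial)
        if not stored:
            raise PipelineError(f"{self.embryo_id}: bundle has no fiducial masks")
        if self.twitch_time_min is None:
            return stored[-1]
        pre = [t for t in stored if self.grid.time_of(t) < self.twitch_time_min]
        if not pre:
            raise PipelineError(f"{self.embryo_id}: no timepoints before twitching")
        return pre[-1]

    # -- persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_nuclei_table(self.nuclei, d / "nuclei.csv")
        for channel, volumes in (("fiducial_gfp", self.fiducial), ("reporter_gfp", self.reporter)):
            cd = d / channel
            cd.mkdir(exist_ok=True)
            for t, vol in volumes.items():
                write_label_volume(vol, cd / f"t{t:03d}.tiff")
        cfg = {
            "embryo_id": self.embryo_id,
            "grid": {
                "shape_voxels": list(self.grid.shape_voxels),
                "voxel_size_um": self.grid.voxel_size_um,
                "slow_interval_min": self.grid.slow_interval_min,
                "fast_interval_min": self.grid.fast_interval_min,
                "slow_count": self.grid.slow_count,
                "fast_count": self.grid.fast_count,
            },
            "twitch_time_min": self.twitch_time_min,
            "fiducial_timepoints": sorted(self.fiducial),
            "reporter_timepoints": sorted(self.reporter),
            "metadata": self.metadata,
        }
        (d / "config.yaml").write_text(yaml.safe_dump(cfg))

    @classmethod
    def load(cls, directory: str | Path) -> "EmbryoBundle":
        d = Path(directory)
        cfg = yaml.safe_load((d / "config.yaml").read_text())
        g = cfg["grid"]
        grid = AcquisitionGrid(
            shape_voxels=tuple(g["shape_voxels"]),
            voxel_size_um=g["voxel_size_um"],
            slow_interval_min=g["slow_interval_min"],
            fast_interval_min=g["fast_interval_min"],
            slow_count=g["slow_count"],
            fast_count=g["fast_count"],
        )
        nuclei = read_nuclei_table(d / "nuclei.csv", grid)
        bundle = cls(
            embryo_id=cfg["embryo_id"],
            grid=grid,
            nuclei=nuclei,
            twitch_time_min=cfg.get("twitch_time_min"),
            metadata=cfg.get("metadata", {}),
        )
        for channel, store in (("fiducial_gfp", bundle.fiducial), ("reporter_gfp", bundle.reporter)):
            for t in cfg.get(f"{channel.split('_')[0]}_timepoints", []):
                store[t] = read_label_volume(d / channel / f"t{t:03d}.tiff", channel, t, grid)
        return bundle
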