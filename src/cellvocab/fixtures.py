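"""Synthetic study fixture: a complete, download-free example dataset.

The generator emulates a two-cell-type automated-microscopy segmentation
study: rat A10 vascular smooth muscle cells seeded at 800 cells/cm2 and
mouse NIH3T3 fibroblasts at 1200 cells/cm2, three replicate wells per type,
fifty fields per well imaged under five Texas Red imaging conditions plus
one DAPI and one phase-contrast pass, one hundred manually segmented cell
masks per type, and seven instrument benchmark images (1 spatial, 4
intensity, 2 resolution).  With the default design that is 750 Texas Red
images per cell type and 2307 image files overall.

Only filename-level manifests and metadata are generated — no pixels.  The
fixture vocabulary mirrors the structure (and, at the default design, the
163-term size) of the full term list of a real prototype cell-image
database; its exact wording is this package's own.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .catalog import Catalog, SeriesEntry
from .ouri import format_unique_id, make_ouri
from .vocabulary import (
    TableRow,
    VocabularyTable,
    build_tree,
    concat_path,
    write_table,
)


@dataclass(frozen=True)
class CellType:
    name: str
    plating_density: str
    organism: str = ""


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of the emulated study; defaults reproduce it exactly."""

    cell_types: tuple[CellType, ...] = (
        CellType("A10", "800 cells/cm2", "rat"),
        CellType("NIH3T3", "1200 cells/cm2", "mouse"),
    )
    wells_per_type: int = 3
    fields_per_well: int = 50
    imaging_conditions: int = 5
    extra_channels: tuple[str, ...] = ("DAPI", "phase")
    masks_per_type: int = 100
    benchmark_counts: tuple[int, int, int] = (1, 4, 2)  # spatial, intensity, resolution
    seed: int = 0
    site_prefix: str = "DEMO"

    def __post_init__(self) -> None:
        counts = (
            self.wells_per_type, self.fields_per_well, self.imaging_conditions,
            self.masks_per_type, *self.benchmark_counts,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all design counts must be non-negative")


def expected_counts(design: StudyDesign) -> dict[str, int]:
    """Closed-form file counts implied by a design."""
    tr = design.fields_per_well * design.imaging_conditions * design.wells_per_type
    per_channel = design.fields_per_well * design.wells_per_type
    n_types = len(design.cell_types)
    benchmarks = sum(design.benchmark_counts)
    total_images = n_types * (
        tr + per_channel * len(design.extra_channels) + design.masks_per_type
    ) + benchmarks
    return {
        "texas_red_per_type": tr,
        "per_extra_channel_per_type": per_channel,
        "masks_per_type": design.masks_per_type,
        "benchmark_images": benchmarks,
        "total_images": total_images,
    }


@dataclass(frozen=True)
class FileRecord:
    filename: str
    series_name: str
    role: str  # image | protocol
    category: str  # texas_red | channel:<name> | mask | benchmark:<kind> | protocol


@dataclass
class StudyFixture:
    design: StudyDesign
    vocabulary: VocabularyTable
    series: list[SeriesEntry] = field(default_factory=list)
    manifest: list[FileRecord] = field(default_factory=list)

    def filenames(self, role: str | None = None) -> list[str]:
        return [r.filename for r in self.manifest
                if role is None or r.role == role]


# ---------------------------------------------------------------------------
# the fixture vocabulary
# ---------------------------------------------------------------------------

# Nested folder structure: dict = interior term, str = example value of a
# token.  Everything hangs under the four root terms.
_STATIC_VOCABULARY: Mapping[str, object] = {
    "study": {
        "title": "Segmentation algorithm comparison study",
        "identifier": "CIDB-0001",
        "abstract_file": "study abstract filename",
        "start_date": "2009-03-01",
        "end_date": "2009-09-30",
        "review_status": "released",
        "location": {
            "institution": "measurement institute",
            "laboratory": "cell systems lab",
            "city": "Springfield",
            "room": "B216",
        },
        "personnel": {
            "investigator": "M. Reyes",
            "experimentalist": "L. Chen",
            "data_manager": "R. Patel",
            "contact_email": "lab@example.org",
        },
        "funding": {
            "agency": "internal",
            "program": "measurement science",
            "grant_number": "n/a",
        },
        "publication": {
            "doi": "10.0000/example",
            "citation": "prototype database report",
        },
        "data_policy": {
            "license": "public domain",
            "embargo_date": "none",
        },
    },
    "cell": {
        "cell_line": "A10",
        "organism": "rat",
        "tissue": "vascular smooth muscle",
        "morphology": "adherent, spread",
        "source": {
            "supplier": "ATCC",
            "catalog_number": "CRL-1476",
            "lot_number": "lot-001",
            "species_verification": "isoenzyme analysis",
        },
        "growth_properties": {
            "doubling_time": "36 h",
            "growth_mode": "monolayer",
        },
        "history": {
            "receipt_date": "2008-11-12",
            "maintenance_culture": {
                "medium": "DMEM",
                "serum": "fetal bovine serum",
                "serum_concentration": "10 %",
                "antibiotic": "penicillin-streptomycin",
                "temperature": "37 C",
                "co2_concentration": "5 %",
                "humidity": "95 %",
                "culture_vessel": "T-75 flask",
                "passaging": {
                    "plating_density": "800 cells/cm2",
                    "passage_number": "12",
                    "confluency_at_passage": "80 %",
                    "detachment_reagent": "trypsin-EDTA",
                    "time_since_seeding": "24 h",
                },
            },
            "cryopreservation": {
                "freezing_medium": "90 % serum, 10 % DMSO",
                "storage_temperature": "-196 C",
                "thaw_date": "2009-01-15",
            },
        },
        "health": {
            "mycoplasma_test": "negative",
            "viability": "95 %",
            "sterility_test": "pass",
        },
    },
    "assay": {
        "datatype": {
            "raw": "unprocessed instrument output",
            "derived": "data computed from raw files",
        },
        "target": {
            "analyte": "cell body protein thiols",
            "label": {
                "fluorophore": "Texas Red-C2-maleimide",
                "excitation_wavelength": "595 nm",
                "emission_wavelength": "620 nm",
                "stock_concentration": "2 mM",
            },
        },
        "reagents": {
            "buffer": "PBS",
            "wash_solution": "PBS + 0.05 % Tween",
            "mounting_medium": "none",
        },
        "preparation": {
            "substrate": "tissue culture polystyrene",
            "coating": "none",
            "seeding_density": "800 cells/cm2",
            "fixation": {
                "fixative": "formaldehyde",
                "fixative_concentration": "1 %",
                "fixation_time": "15 min",
                "fixation_temperature": "room temperature",
            },
            "permeabilization": "none",
            "staining": {
                "stain": "Texas Red-C2-maleimide",
                "stain_concentration": "0.2 uM",
                "incubation_time": "30 min",
                "counterstain": "DAPI",
            },
        },
        "image series details": {
            "collection basis": {
                "modality": "automated epifluorescence and phase contrast",
                "objective_magnification": "10x",
                "fields_per_well": "50",
                "wells_per_plate": "6",
                "replicate_wells": "3",
                # "imaging condition" subtree appended per design
            },
            "channel": {
                "channel_name": "Texas Red",
                "exposure_time": "150 ms",
                "filter_set": "TRITC cube",
                "z_position": "autofocus plane",
            },
            "image_format": "TIF",
            "bit_depth": "12",
            "image_width": "1392",
            "image_height": "1040",
            "time_stamp_format": "ISO 8601",
        },
        "segmentation": {
            "method": "manual segmentation",
            "operator": "trained analyst",
            "mask_count": "100",
        },
    },
    "instrument": {
        "microscope": {
            "manufacturer": "microscope vendor",
            "model": "inverted epifluorescence stand",
            "serial_number": "SN-0001",
            "stage": "motorized xy stage",
            "automation": "scripted acquisition",
        },
        "optics": {
            "objective": {
                "magnification": "10x",
                "numerical_aperture": "0.3",
                "immersion": "air",
            },
            "filter_cube": "TRITC / DAPI / phase",
        },
        "camera": {
            "sensor_type": "cooled CCD",
            "pixel_size": "6.45 um",
            "gain": "1",
            "binning": "1x1",
        },
        "illumination": {
            "source": "metal halide lamp",
            "wavelength": "broadband",
            "intensity": "50 %",
            "exposure_control": "shutter",
        },
        "environmental_control": {
            "temperature": "ambient",
            "co2": "none",
            "humidity_control": "none",
        },
        "benchmark": {
            "spatial": {
                "target_type": "stage micrometer",
                "grid_spacing": "10 um",
            },
            "intensity": {
                "material": "fluorescent reference glass",
                "reference_level": "4 steps",
            },
            "resolution": {
                "target_type": "USAF 1951 target",
                "line_spacing": "varied",
            },
        },
        "software": {
            "acquisition_software": "scripted acquisition suite",
            "analysis_software": "segmentation toolbox",
            "version": "1.0",
        },
    },
}

COLLECTION_BASIS = ("assay", "image series details", "collection basis")
IMAGING_CONDITION = COLLECTION_BASIS + ("imaging condition",)


def _walk_static(
    prefix: tuple[str, ...], node: Mapping[str, object]
) -> Iterator[TableRow]:
    for label, value in node.items():
        path = prefix + (label,)
        if isinstance(value, Mapping):
            yield from _walk_static(path, value)
        else:
            yield TableRow(path[:-1], path[-1], str(value))


def condition_label(i: int) -> str:
    return f"c{i}"


def default_vocabulary(design: StudyDesign) -> VocabularyTable:
    """Row-per-token vocabulary table for a design.

    The static term list plus one ``imaging condition`` token per condition
    in the design; the default design yields a 163-term tree.
    """
    rows = list(_walk_static((), _STATIC_VOCABULARY))
    for i in range(1, design.imaging_conditions + 1):
        rows.append(
            TableRow(
                IMAGING_CONDITION,
                condition_label(i),
                f"Texas Red exposure/filter variant {i}",
            )
        )
    return VocabularyTable(rows)


# ---------------------------------------------------------------------------
# series metadata
# ---------------------------------------------------------------------------

def _shared_metadata(design: StudyDesign) -> dict[str, str]:
    # identical for every series: study- and instrument-rooted context
    return {
        "study:title": "Segmentation algorithm comparison study",
        "study:identifier": "CIDB-0001",
        "study:personnel:investigator": "M. Reyes",
        "study:personnel:experimentalist": "L. Chen",
        "instrument:microscope:manufacturer": "microscope vendor",
        "instrument:microscope:model": "inverted epifluorescence stand",
        "instrument:optics:objective:magnification": "10x",
        "instrument:optics:objective:numerical_aperture": "0.3",
        "instrument:camera:sensor_type": "cooled CCD",
        "instrument:camera:pixel_size": "6.45 um",
        "instrument:illumination:source": "metal halide lamp",
    }


def _well_metadata(
    design: StudyDesign, cell: CellType, rng: random.Random
) -> dict[str, str]:
    md = _shared_metadata(design)
    md.update({
        "cell:cell_line": cell.name,
        "cell:organism": cell.organism,
        "cell:history:maintenance_culture:medium": "DMEM",
        "cell:history:maintenance_culture:passaging:plating_density":
            cell.plating_density,
        "cell:history:maintenance_culture:passaging:passage_number":
            str(rng.randint(5, 25)),
        "assay:datatype": "raw",
        "assay:preparation:seeding_density": cell.plating_density,
        "assay:preparation:fixation:fixative": "formaldehyde",
        "assay:preparation:staining:stain": "Texas Red-C2-maleimide",
        "assay:preparation:staining:counterstain": "DAPI",
        concat_path(COLLECTION_BASIS + ("modality",)):
            "automated epifluorescence and phase contrast",
        concat_path(COLLECTION_BASIS + ("objective_magnification",)): "10x",
        concat_path(COLLECTION_BASIS + ("fields_per_well",)):
            str(design.fields_per_well),
        concat_path(COLLECTION_BASIS + ("replicate_wells",)):
            str(design.wells_per_type),
    })
    for i in range(1, design.imaging_conditions + 1):
        md[concat_path(IMAGING_CONDITION + (condition_label(i),))] = (
            f"exposure {rng.choice([30, 50, 100, 150, 300])} ms, "
            f"filter variant {i}"
        )
    return md


def _mask_metadata(design: StudyDesign, cell: CellType) -> dict[str, str]:
    md = _shared_metadata(design)
    md.update({
        "cell:cell_line": cell.name,
        "cell:organism": cell.organism,
        "assay:datatype": "derived",
        "assay:segmentation:method": "manual segmentation",
        "assay:segmentation:mask_count": str(design.masks_per_type),
    })
    return md


def _benchmark_metadata(design: StudyDesign) -> dict[str, str]:
    md = _shared_metadata(design)
    md.update({
        "assay:datatype": "raw",
        "instrument:benchmark:spatial:target_type": "stage micrometer",
        "instrument:benchmark:intensity:material": "fluorescent reference glass",
        "instrument:benchmark:resolution:target_type": "USAF 1951 target",
    })
    return md


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_study_fixture(design: StudyDesign | None = None) -> StudyFixture:
    """Generate vocabulary, series metadata and the OURI file manifest.

    One metadata series per (cell type, well) carries the Texas Red, DAPI
    and phase images of that well; each cell type additionally gets one
    derived-data series holding its masks (content code ``D``,
    ``assay:datatype`` = ``derived``), and the benchmark images live in one
    dedicated instrument-benchmark series (content code ``R``).  Every
    series links exactly one protocol file.  Same seed, same fixture.
    """
    design = design or StudyDesign()
    rng = random.Random(design.seed)
    fixture = StudyFixture(design, default_vocabulary(design))
    uid_counter = 0

    def next_uid() -> str:
        nonlocal uid_counter
        uid_counter += 1
        return format_unique_id(design.site_prefix, uid_counter)

    def new_series(name: str, metadata: dict[str, str]) -> tuple[SeriesEntry, int]:
        entry = SeriesEntry(name, metadata)
        fixture.series.append(entry)
        return entry, len(fixture.series)

    def add_file(entry: SeriesEntry, series_no: int, code: str, region: str,
                 ext: str, role: str, category: str) -> None:
        filename = make_ouri(code, region, next_uid(), series_no, ext)
        entry.files(role).append(filename)
        fixture.manifest.append(
            FileRecord(filename, entry.series_name, role, category)
        )

    for cell in design.cell_types:
        for well in range(1, design.wells_per_type + 1):
            entry, sno = new_series(
                f"{cell.name}_well{well}", _well_metadata(design, cell, rng)
            )
            for cond in range(1, design.imaging_conditions + 1):
                for fov in range(1, design.fields_per_well + 1):
                    add_file(
                        entry, sno, "I",
                        f"{cell.name}-w{well}-c{cond}-f{fov:03d}-TexasRed",
                        ".tif", "image", "texas_red",
                    )
            for channel in design.extra_channels:
                for fov in range(1, design.fields_per_well + 1):
                    add_file(
                        entry, sno, "I",
                        f"{cell.name}-w{well}-f{fov:03d}-{channel}",
                        ".tif", "image", f"channel:{channel}",
                    )
            add_file(entry, sno, "P", f"{cell.name}-w{well}-protocol",
                     ".txt", "protocol", "protocol")

        entry, sno = new_series(
            f"{cell.name}_masks", _mask_metadata(design, cell)
        )
        for m in range(1, design.masks_per_type + 1):
            add_file(entry, sno, "D", f"{cell.name}-mask-{m:03d}",
                     ".tif", "image", "mask")
        add_file(entry, sno, "P", f"{cell.name}-masks-protocol",
                 ".txt", "protocol", "protocol")

    entry, sno = new_series("instrument_benchmarks", _benchmark_metadata(design))
    for kind, count in zip(
        ("spatial", "intensity", "resolution"), design.benchmark_counts
    ):
        for i in range(1, count + 1):
            add_file(entry, sno, "R", f"benchmark-{kind}-{i}",
                     ".tif", "image", f"benchmark:{kind}")
    add_file(entry, sno, "P", "benchmark-protocol", ".txt", "protocol", "protocol")

    return fixture


def load_fixture_into_catalog(fixture: StudyFixture) -> Catalog:
    """Build the vocabulary tree and register every series and file.

    Registration runs under the strict policy: the fixture vocabulary must
    already cover every metadata key it emits.  The returned catalog passes
    referential-integrity validation.
    """
    catalog = Catalog(build_tree(fixture.vocabulary, on_collision="error"))
    for entry in fixture.series:
        catalog.register_series(entry.series_name, entry.metadata, policy="strict")
        if entry.image_files:
            catalog.register_files(entry.series_name, entry.image_files, "image")
        if entry.protocol_files:
            catalog.register_files(
                entry.series_name, entry.protocol_files, "protocol"
            )
    catalog.check()
    return catalog


def write_fixture(
    fixture: StudyFixture,
    directory: str | Path,
    protocol_stubs: bool = False,
) -> Catalog:
    """Write the fixture to disk: catalog CSVs, a manifest CSV and,
    optionally, zero-length-content protocol stub text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    catalog = load_fixture_into_catalog(fixture)
    catalog.save(directory)
    write_table(fixture.vocabulary, directory / "vocabulary_table.csv")
    import csv as _csv

    with open(directory / "manifest.csv", "w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(["filename", "series_name", "role", "category"])
        for rec in fixture.manifest:
            w.writerow([rec.filename, rec.series_name, rec.role, rec.category])
    if protocol_stubs:
        stub_dir = directory / "protocols"
        stub_dir.mkdir(exist_ok=True)
        for rec in fixture.manifest:
            if rec.role == "protocol":
                (stub_dir / rec.filename).write_text(
                    f"Protocol stub for series {rec.series_name}.\n",
                    encoding="utf-8",
                )
    return catalog
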