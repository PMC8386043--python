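"""Reading and writing a practical subset of the RDML format, flat
instrument tables and annotated result tables.

RDML stores one qPCR run as a zip archive containing a predefined
XML document (``rdml_data.xml``).  This module writes RDML v1.2 element
names and reads any v1.1-v1.3 file by tolerant, namespace-agnostic element
lookup; versions below 1.1 are rejected.  Analysis results (per-target
efficiency, the run threshold, per-reaction Cq/N0 and the melting correction
factor) are written back into the file; the correction factor lives in a
``corrF`` child of the reaction data element, a documented convention for
schema versions without a dedicated field.

Numeric values are serialized with ``repr`` so that read(write(run)) is
field-exact, and raw fluorescence series are never mutated by any I/O
operation.
"""

from __future__ import annotations

import csv
import io
import logging
import zipfile

from lxml import etree

from .amplification import AmplificationAnalysis
from .data import ReactionRecord, RunData, SampleInfo, TargetInfo
from .errors import (
    RdmlFormatError,
    RdmlStructureError,
    TableFormatError,
    TableParseError,
    UnsupportedVersionError,
)
from .melting import MeltResult

log = logging.getLogger(__name__)

RDML_NS = "http://www.rdml.org"
RDML_VERSION = "1.2"
ARCHIVE_NAME = "rdml_data.xml"

_TYPE_TO_RDML = {"unknown": "unkn", "positive_control": "pos",
                 "negative_control": "ntc"}
_TYPE_FROM_RDML = {"unkn": "unknown", "pos": "positive_control",
                   "ntc": "negative_control", "neg": "negative_control",
                   "std": "unknown", "opt": "unknown", "ref": "unknown"}
_TYPE_FROM_RDML.update({v: v for v in _TYPE_TO_RDML})


def _local(el) -> str:
    return etree.QName(el).localname


def _children(el, name):
    return [c for c in el if isinstance(c.tag, str) and _local(c) == name]

def _child(el, name):
    found = _children(el, name)
    return found[0] if found else None


def _text(el, name, default=None):
    c = _child(el, name)
    if c is None or c.text is None:
        return default
    return c.text.strip()


def _require(el, name, context):
    c = _child(el, name)
    if c is None:
        raise RdmlStructureError(
            f"missing required element <{name}> under <{context}>")
    return c


# ---------------------------------------------------------------------------
# reading


def read_rdml(path) -> RunData:
    """Read a RunData from an RDML zip archive.

    Raw adp/mdp series are returned exactly as stored (never
    baseline-corrected).  Raises :class:`RdmlFormatError` for non-zip input,
    :class:`RdmlStructureError` for missing elements and
    :class:`UnsupportedVersionError` for RDML versions below 1.1.
    """
    root = _load_root(path)
    version = root.get("version", "")
    try:
        if float(version) < 1.1:
            raise UnsupportedVersionError(
                f"RDML version {version}: version 1.1 or higher is required")
    except ValueError:
        raise RdmlStructureError(f"unparseable RDML version {version!r}")

    run = RunData(run_id="")
    for s in _children(root, "sample"):
        sid = s.get("id")
        if sid is None:
            raise RdmlStructureError("missing id attribute on <sample>")
        stype = _text(s, "type", "unkn")
        run.samples[sid] = SampleInfo(sid, _TYPE_FROM_RDML.get(stype, "unknown"))
    for t in _children(root, "target"):
        tid = t.get("id")
        if tid is None:
            raise RdmlStructureError("missing id attribute on <target>")
        tm = _text(t, "meltingTemperature")
        sat = _text(t, "dyeSaturating", "false")
        run.targets[tid] = TargetInfo(
            tid,
            expected_tm=float(tm) if tm is not None else None,
            dye_saturating=(sat.lower() == "true"),
        )
    experiment = _require(root, "experiment", "rdml")
    run_el = _require(experiment, "run", "experiment")
    run.run_id = run_el.get("id", "run1")
    for react in _children(run_el, "react"):
        well = react.get("id")
        if well is None:
            raise RdmlStructureError("missing id attribute on <react>")
        sample_el = _require(react, "sample", f"react {well}")
        data = _require(react, "data", f"react {well}")
        tar = _require(data, "tar", f"data of react {well}")
        rec = ReactionRecord(well, sample_el.get("id", ""), tar.get("id", ""))
        for adp in _children(data, "adp"):
            cyc = _text(adp, "cyc")
            fluor = _text(adp, "fluor")
            if cyc is None or fluor is None:
                raise RdmlStructureError(
                    f"react {well}: <adp> without <cyc>/<fluor>")
            rec.adp.append((int(float(cyc)), float(fluor)))
        for mdp in _children(data, "mdp"):
            tmp = _text(mdp, "tmp")
            fluor = _text(mdp, "fluor")
            if tmp is None or fluor is None:
                raise RdmlStructureError(
                    f"react {well}: <mdp> without <tmp>/<fluor>")
            rec.mdp.append((float(tmp), float(fluor)))
        run.reactions.append(rec)
    return run


def _load_root(path):
    if not zipfile.is_zipfile(path):
        raise RdmlFormatError(f"{path}: not a zip archive (RDML requires zip)")
    with zipfile.ZipFile(path) as zf:
        names = zf.namelist()
        if ARCHIVE_NAME in names:
            xml_name = ARCHIVE_NAME
        else:
            xmls = [n for n in names if n.endswith(".xml")]
            if len(xmls) != 1:
                raise RdmlStructureError(
                    f"{path}: archive does not contain {ARCHIVE_NAME}")
            xml_name = xmls[0]
        try:
            root = etree.fromstring(zf.read(xml_name))
        except etree.XMLSyntaxError as exc:
            raise RdmlStructureError(f"{path}: invalid XML: {exc}")
    if _local(root) != "rdml":
        raise RdmlStructureError(f"{path}: root element is not <rdml>")
    return root


def read_stored_results(path) -> dict:
    """Read analysis results previously stored in an RDML file.

    Returns ``{"threshold": float | None, "targets": {id: {"efficiency"}},
    "reactions": {well: {"cq", "n0", "corr_f", "corrected_cq",
    "corrected_n0"}}}`` with absent values omitted.
    """
    root = _load_root(path)
    out: dict = {"threshold": None, "targets": {}, "reactions": {}}
    experiment = _require(root, "experiment", "rdml")
    run_el = _require(experiment, "run", "experiment")
    thr = _text(run_el, "quantificationThreshold")
    if thr is not None:
        out["threshold"] = float(thr)
    for t in _children(root, "target"):
        eff = _text(t, "pcrEfficiency")
        if eff is not None:
            out["targets"][t.get("id")] = {"efficiency": float(eff)}
    for react in _children(run_el, "react"):
        data = _child(react, "data")
        if data is None:
            continue
        entry = {}
        for xml_name, key in (("cq", "cq"), ("N0", "n0"), ("corrF", "corr_f"),
                              ("corrCq", "corrected_cq"),
                              ("corrN0", "corrected_n0")):
            v = _text(data, xml_name)
            if v is not None:
                entry[key] = float(v)
        if entry:
            out["reactions"][react.get("id")] = entry
    return out


# ---------------------------------------------------------------------------
# writing


def write_rdml(run: RunData, path,
               amp_results: AmplificationAnalysis | None = None,
               melt_results: dict[str, MeltResult] | None = None) -> None:
    """Write a RunData (and optional analysis results) as an RDML archive.

    The run is validated against its invariants before anything is written.
    """
    run.validate()
    nsmap = {None: RDML_NS}
    root = etree.Element(f"{{{RDML_NS}}}rdml", nsmap=nsmap, version=RDML_VERSION)

    def sub(parent, name, text=None, **attrs):
        el = etree.SubElement(parent, f"{{{RDML_NS}}}{name}", **attrs)
        if text is not None:
            el.text = text
        return el

    for sid in run.samples:
        s = run.samples[sid]
        el = sub(root, "sample", id=sid)
        sub(el, "type", _TYPE_TO_RDML[s.sample_type])
    for tid in run.targets:
        t = run.targets[tid]
        el = sub(root, "target", id=tid)
        if t.expected_tm is not None:
            sub(el, "meltingTemperature", repr(t.expected_tm))
        sub(el, "dyeSaturating", "true" if t.dye_saturating else "false")
        if amp_results is not None and tid in amp_results.assays:
            sub(el, "pcrEfficiency", repr(amp_results.assays[tid].e_tar))
    experiment = sub(root, "experiment", id="experiment1")
    run_el = sub(experiment, "run", id=run.run_id)
    if amp_results is not None:
        sub(run_el, "quantificationThreshold", repr(amp_results.threshold.nq))
    for rec in run.reactions:
        react = sub(run_el, "react", id=rec.well)
        sub(react, "sample", id=rec.sample_id)
        data = sub(react, "data")
        sub(data, "tar", id=rec.target_id)
        if amp_results is not None and rec.well in amp_results.reactions:
            rr = amp_results.reactions[rec.well]
            if rr.cq is not None:
                sub(data, "cq", repr(rr.cq))
            if rr.n0 is not None:
                sub(data, "N0", repr(rr.n0))
        if melt_results is not None and rec.well in melt_results:
            mr = melt_results[rec.well]
            if mr.correction_factor is not None:
                sub(data, "corrF", repr(mr.correction_factor))
            if mr.corrected_cq is not None:
                sub(data, "corrCq", repr(mr.corrected_cq))
            if mr.corrected_n0 is not None:
                sub(data, "corrN0", repr(mr.corrected_n0))
        for cyc, fluor in rec.adp:
            adp = sub(data, "adp")
            sub(adp, "cyc", repr(cyc))
            sub(adp, "fluor", repr(fluor))
        for tmp, fluor in rec.mdp:
            mdp = sub(data, "mdp")
            sub(mdp, "tmp", repr(tmp))
            sub(mdp, "fluor", repr(fluor))
    payload = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                             pretty_print=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(ARCHIVE_NAME, payload)


# ---------------------------------------------------------------------------
# flat instrument tables


class TableLayout:
    """Column/orientation description of an exported instrument table.

    ``orientation``: 'long' (well, cycle, fluorescence triples) or 'wide'
    (one column per well, first column the cycle axis).  ``kind``: 'adp'
    (cycle axis) or 'mdp' (temperature axis).  ``annotations`` maps well to
    a dict with optional 'sample', 'target' and 'sample_type' entries; wells
    without annotation default to an unknown sample (logged).
    """

    def __init__(self, orientation: str = "long", kind: str = "adp",
                 well_col: str = "well", axis_col: str | None = None,
                 fluor_col: str = "fluor", sample_col: str | None = None,
                 target_col: str | None = None, type_col: str | None = None,
                 annotations: dict | None = None, delimiter: str = ",",
                 default_target: str = "target1"):
        if orientation not in ("long", "wide"):
            raise TableFormatError(f"unknown orientation {orientation!r}")
        if kind not in ("adp", "mdp"):
            raise TableFormatError(f"unknown table kind {kind!r}")
        self.orientation = orientation
        self.kind = kind
        self.well_col = well_col
        self.axis_col = axis_col or ("cycle" if kind == "adp" else "temperature")
        self.fluor_col = fluor_col
        self.sample_col = sample_col
        self.target_col = target_col
        self.type_col = type_col
        self.annotations = annotations or {}
        self.delimiter = delimiter
        self.default_target = default_target


def _read_rows(source, delimiter):
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, newline="") as fh:
            text = fh.read()
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if r]
    if not rows:
        raise TableFormatError("empty table")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise TableFormatError(f"ragged rows: widths {sorted(widths)}")
    return rows


def _to_float(value, row, col):
    try:
        return float(value)
    except ValueError:
        raise TableParseError(
            f"non-numeric fluorescence {value!r} at row {row}, column {col}",
            row=row, column=col)


def import_table(source, layout: TableLayout | None = None,
                 run_id: str = "imported") -> RunData:
    """Build a RunData from a rectangular instrument export.

    Long and wide renderings of the same plate yield identical RunData.
    Unannotated reactions default to sample_type 'unknown' with a logged
    warning.
    """
    layout = layout or TableLayout()
    rows = _read_rows(source, layout.delimiter)
    header = rows[0]
    run = RunData(run_id=run_id)
    series: dict[str, list[tuple[float, float]]] = {}
    meta: dict[str, dict] = {}

    if layout.orientation == "long":
        def col(name, required=True):
            if name in header:
                return header.index(name)
            if required:
                raise TableFormatError(f"missing column {name!r} in {header}")
            return None

        iw = col(layout.well_col)
        ia = col(layout.axis_col)
        if_ = col(layout.fluor_col)
        is_ = col(layout.sample_col, required=False) if layout.sample_col else None
        it = col(layout.target_col, required=False) if layout.target_col else None
        ity = col(layout.type_col, required=False) if layout.type_col else None
        for rix, row in enumerate(rows[1:], start=2):
            well = row[iw]
            axis = _to_float(row[ia], rix, layout.axis_col)
            fluor = _to_float(row[if_], rix, layout.fluor_col)
            series.setdefault(well, []).append((axis, fluor))
            m = meta.setdefault(well, {})
            if is_ is not None:
                m["sample"] = row[is_]
            if it is not None:
                m["target"] = row[it]
            if ity is not None:
                m["sample_type"] = row[ity]
    else:  # wide: first matching column is the axis, every other column a well
        if layout.axis_col not in header:
            raise TableFormatError(
                f"missing column {layout.axis_col!r} in {header}")
        ia = header.index(layout.axis_col)
        wells = [h for i, h in enumerate(header) if i != ia]
        for rix, row in enumerate(rows[1:], start=2):
            axis = _to_float(row[ia], rix, layout.axis_col)
            for i, h in enumerate(header):
                if i == ia:
                    continue
                series.setdefault(h, []).append(
                    (axis, _to_float(row[i], rix, h)))
        for w in wells:
            meta.setdefault(w, {})

    for well in series:
        m = {**meta.get(well, {}), **layout.annotations.get(well, {})}
        sample = m.get("sample", well)
        target = m.get("target", layout.default_target)
        stype = m.get("sample_type")
        if stype is None:
            stype = "unknown"
            log.warning("well %s: no sample-type annotation, defaulting to "
                        "'unknown'", well)
        if sample not in run.samples:
            run.samples[sample] = SampleInfo(sample, stype)
        if target not in run.targets:
            run.targets[target] = TargetInfo(target)
        rec = ReactionRecord(well, sample, target)
        pts = series[well]
        if layout.kind == "adp":
            rec.adp = [(int(a), f) for a, f in pts]
        else:
            rec.mdp = [(a, f) for a, f in pts]
        run.reactions.append(rec)
    run.reactions.sort(key=lambda r: r.well)
    run.validate()
    return run


# ---------------------------------------------------------------------------
# result export


_AMP_COLUMNS = ["well", "sample", "sample_type", "target", "e_tar", "indiv_E",
                "cq", "n0", "flags", "messages"]
_MELT_COLUMNS = ["well", "sample", "sample_type", "target", "peak", "tm",
                 "delta_height", "width", "fluorescence", "fraction",
                 "is_expected", "correction_factor", "corrected_cq",
                 "corrected_n0", "flags", "messages"]


def _fmt(value):
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def export_results_csv(run: RunData,
                       amp_results: AmplificationAnalysis | None,
                       melt_results: dict[str, MeltResult] | None,
                       path, melt_path=None) -> list:
    """Write annotated result tables as CSV (UTF-8, '.' decimals, ','
    delimiter; flags ';'-joined).

    The amplification table at ``path`` has one row per reaction; the melting
    table (``melt_path``, default derived from ``path``) has one row per
    retained peak (or one flag-only row for reactions without peaks).
    Returns the list of paths written.
    """
    written = []
    if amp_results is not None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_AMP_COLUMNS)
            for well in sorted(amp_results.reactions):
                rr = amp_results.reactions[well]
                assay = amp_results.assays.get(rr.target_id)
                w.writerow([
                    rr.well, rr.sample_id, rr.sample_type, rr.target_id,
                    _fmt(assay.e_tar if assay else None),
                    _fmt(rr.indiv_efficiency),
                    _fmt(rr.cq), _fmt(rr.n0),
                    ";".join(sorted(rr.flags)),
                    ";".join(rr.messages),
                ])
        written.append(path)
    if melt_results is not None:
        if melt_path is None:
            base = str(path)
            melt_path = (base[:-4] + "_melt.csv") if base.endswith(".csv") \
                else base + "_melt.csv"
        stypes = {r.well: run.samples[r.sample_id].sample_type
                  for r in run.reactions}
        with open(melt_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_MELT_COLUMNS)
            for well in sorted(melt_results):
                mr = melt_results[well]
                common = [mr.well, mr.sample_id, stypes.get(well, ""),
                          mr.target_id]
                if not mr.peaks:
                    w.writerow(common + [""] * 10
                               + [";".join(sorted(mr.flags)),
                                  ";".join(mr.messages)])
                    continue
                for i, p in enumerate(mr.peaks, start=1):
                    w.writerow(common + [
                        i, _fmt(p.tm), _fmt(p.delta_height), _fmt(p.width),
                        _fmt(p.fluorescence), _fmt(p.fraction),
                        str(p.is_expected).lower(),
                        _fmt(mr.correction_factor if p.is_expected else None),
                        _fmt(mr.corrected_cq if p.is_expected else None),
                        _fmt(mr.corrected_n0 if p.is_expected else None),
                        ";".join(sorted(mr.flags)),
                        ";".join(mr.messages),
                    ])
        written.append(melt_path)
    return written
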