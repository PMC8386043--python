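"""Import raw fluorescence from a plain instrument export.

Many qPCR machines only export spreadsheets.  A TableLayout describes the
orientation (long: well,cycle,fluor rows; wide: one column per well) and
where the sample/target/sample-type annotation lives; both renderings of the
same plate produce identical RunData, which can then be written out as RDML.
"""

import io

from ampliquant import TableLayout, import_table, write_rdml

long_text = """well,cycle,fluor,sample,target,sample_type
A1,1,50.1,liver,GAPDH,unknown
A1,2,50.2,liver,GAPDH,unknown
A1,3,50.5,liver,GAPDH,unknown
B1,1,49.8,water,GAPDH,negative_control
B1,2,49.9,water,GAPDH,negative_control
B1,3,49.7,water,GAPDH,negative_control
"""

wide_text = """cycle,A1,B1
1,50.1,49.8
2,50.2,49.9
3,50.5,49.7
"""

long_run = import_table(io.StringIO(long_text), TableLayout(
    orientation="long", sample_col="sample", target_col="target",
    type_col="sample_type"))
wide_run = import_table(io.StringIO(wide_text), TableLayout(
    orientation="wide",
    annotations={
        "A1": {"sample": "liver", "target": "GAPDH", "sample_type": "unknown"},
        "B1": {"sample": "water", "target": "GAPDH",
               "sample_type": "negative_control"},
    }))

print("long == wide:", long_run == wide_run)
print("wells:", [r.well for r in long_run.reactions])
print("sample types:", {s.sample_id: s.sample_type
                        for s in long_run.samples.values()})
write_rdml(long_run, "imported.rdml")
print("wrote imported.rdml")
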