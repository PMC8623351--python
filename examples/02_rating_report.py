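"""Write a calibration report and render the rating-light matrix.

The report serializes every labeled (muscle, electrode, amplitude) cell
with its features, the candidate ranking and both recommendations; the
text rendering mirrors the rating-light / rating-details matrices.
"""

import tempfile
from pathlib import Path

from tscscal import (
    ProtocolConfig,
    calibrate_session,
    default_ground_truth,
    generate_session,
    read_report,
    render_details,
    render_rating_light,
    write_result,
)

protocol = ProtocolConfig(electrode_positions=(1, 2, 3), amplitude_grid_mA=tuple(range(5, 80, 5)))
truth = default_ground_truth(seed=2, protocol=protocol, best_electrode=2)
result = calibrate_session(generate_session(truth, protocol), protocol)

out = Path(tempfile.mkdtemp()) / "report"
json_path, csv_path = write_result(result, out, protocol=protocol)
print(f"wrote {json_path} and {csv_path}\n")

d = read_report(json_path)
print(render_rating_light(d))
print()
print(render_details(d))
# Each cell shows one glyph per muscle (LQ, LTS, RQ, RTS):
# . = no response, G = reflex (green), Y = presumed M-wave, R = invalid.
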