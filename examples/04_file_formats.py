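"""Write and read every data-file format.

Builds a tiny two-rat synthetic cohort, writes the per-rat data CSVs,
listfile and parameter listfile, fits one rat and writes the 46-column
estimated-parameters file, then writes the per-rat summary (A/E/. codes)
and a simulation-output file, reading each back to show the round trip.
"""

import tempfile
from pathlib import Path

from avoidrl import GridSpec, ModelParameters, TaskConfig, fit_grid, \
    simulate_rat
from avoidrl import io_formats as io
from avoidrl.synthetic_data import default_cohort, write_cohort

config = TaskConfig(n_sessions=2, trials_per_session=5, homecage_steps=40)
with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    spec = default_cohort(n_per_strain=1, config=config)
    paths = write_cohort(spec, tmp)
    rats = io.read_listfile(paths["listfile"])
    print("cohort rats:", rats)

    data = io.read_rat_csv(paths[rats[0]])
    print(f"{data.rat_id}: {len(data)} timesteps read back and validated")

    fit = fit_grid(data, GridSpec.singleton(ModelParameters()), config)
    io.write_estimated_parms([fit], tmp / "estimated_parms.csv")
    df = io.read_estimated_parms(tmp / "estimated_parms.csv")
    print(f"estimated_parms.csv: {df.shape[1] + 1} columns "
          f"(7 params, negLLE, 10 M, 5 V, 21 grid, overnight)")

    io.write_summary_file(data, tmp / f"{data.rat_id}sum.csv", config)
    table = io.read_summary_file(tmp / f"{data.rat_id}sum.csv")
    print(f"summary file: outcomes per session = {[''.join(r) for r in table.outcomes]}")

    sim = simulate_rat(ModelParameters(), config, n_runs=3, seed=1)
    io.write_simulation_output(sim, tmp / "S09out.csv")
    runs = io.read_simulation_output(tmp / "S09out.csv")
    print(f"simulation output: {len(runs)} runs round-tripped "
          f"(headers like 2_3_1_ITRs = session 2, trial 3, minute 1)")
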