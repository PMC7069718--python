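"""Threshold nonlinearities sharpen — and decorrelate — dendritic tuning.

Runs the stochastic multi-compartment ganglion-cell model (177 E/I
synapse pairs, moving edge at 1 mm/s) and reads out each dendritic
site's tuning from the voltage integrated above increasingly strict
thresholds.  Stricter thresholds raise the mean DSI while single-set
preferred directions disperse (higher sigma_theta): a threshold
nonlinearity turns shared stochastic release noise into site-to-site
tuning differences.
"""

from dsgcdend import run_model_experiment

report = run_model_experiment({"seed": 1, "n_sets": 5})
print(report.table.to_string(index=False,
                             formatters={"mean_dsi": "{:.2f}".format,
                                         "sigma_theta_deg": "{:.1f}".format}))
print("DSI monotone increasing:", report.trend["dsi_monotone_increasing"])
print("sigma_theta non-decreasing:", report.trend["sigma_theta_nondecreasing"])
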