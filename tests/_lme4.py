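"""Drive R's lme4 as an independent weighted-REML oracle (one Rscript call)."""

from __future__ import annotations

import csv
import json
import subprocess
from pathlib import Path

_R_SCRIPT = r"""
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
out <- list()
for (ds in unique(d$dataset)) {
  sub <- d[d$dataset == ds, ]
  fit <- lmer(y ~ x + (1 | study), data = sub, weights = w, REML = TRUE,
              control = lmerControl(optimizer = "bobyqa",
                                    optCtrl = list(maxfun = 1e5),
                                    check.conv.singular = "ignore"))
  vc <- as.data.frame(VarCorr(fit))
  out[[as.character(ds)]] <- list(
    beta0 = unname(fixef(fit)[1]),
    beta1 = unname(fixef(fit)[2]),
    tau2 = vc$vcov[vc$grp == "study"],
    sigma2 = sigma(fit)^2
  )
}
cat(toJSON(out, auto_unbox = TRUE, digits = 12))
"""


def lme4_fits(datasets, workdir: Path) -> dict:
    """Fit y ~ x + (1|study) with weights for each (y, x, w, study) dataset.

    ``datasets`` maps a name to a dict of equal-length sequences; returns
    {name: {beta0, beta1, tau2, sigma2}}.
    """
    csv_path = workdir / "lme4_input.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dataset", "y", "x", "w", "study"])
        for name, d in datasets.items():
            for y, x, w, s in zip(d["y"], d["x"], d["w"], d["study"]):
                writer.writerow([name, repr(float(y)), repr(float(x)), int(w), s])
    script = workdir / "lme4_oracle.R"
    script.write_text(_R_SCRIPT)
    res = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv_path)],
        capture_output=True,
        text=True,
        timeout=600,
    )
    if res.returncode != 0:
        raise RuntimeError(f"lme4 oracle failed: {res.stderr[-2000:]}")
    return json.loads(res.stdout)
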