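"""glmmTMB backend: batch GLMM fitting through an Rscript subprocess.

The mixed models (gaussian, Gamma-log, negative-binomial-log with a fish
random intercept and optionally a random slope over background) are fitted
by the glmmTMB R package.  Python builds the fixed-effect design matrix and
passes it with the raw grouping/slope columns; R fits
``y ~ 0 + X... + (1 | group)`` (or ``(1 + slope_factor | group)``) and
returns estimates, covariance, variance components and diagnostics as JSON.
Several datasets are fitted in a single R session, since interpreter
startup dominates the cost of one fit.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from pathlib import Path

__all__ = ["run_glmm_jobs", "RGlmmError"]


class RGlmmError(RuntimeError):
    """The R backend failed to produce a usable fit."""


_R_SCRIPT = r"""
suppressMessages(library(glmmTMB))
suppressMessages(library(jsonlite))

args <- commandArgs(trailingOnly = TRUE)
jobs <- fromJSON(args[[1]], simplifyDataFrame = FALSE)
out <- vector("list", length(jobs))

fam_of <- function(name) {
  switch(name,
    gaussian = gaussian(),
    gamma = Gamma(link = "log"),
    negbin = nbinom2(link = "log"),
    stop("unknown family: ", name))
}

fit_one <- function(d, job, random_kind) {
  xcols <- unlist(job$x_cols)
  fixed <- paste0("`", xcols, "`", collapse = " + ")
  re <- if (random_kind == "slope") {
    sprintf("(1 + %s | %s)", job$slope_factor, job$group)
  } else {
    sprintf("(1 | %s)", job$group)
  }
  form <- as.formula(paste0("`", job$response, "` ~ 0 + ", fixed, " + ", re))
  glmmTMB(form, data = d, family = fam_of(job$family))
}

extract <- function(m, job, random_kind) {
  beta <- fixef(m)$cond
  V <- as.matrix(vcov(m)$cond)
  vc <- VarCorr(m)$cond[[job$group]]
  Sig <- matrix(as.numeric(vc), nrow = nrow(vc),
                dimnames = list(rownames(vc), colnames(vc)))
  # mean random-effect variance over the observed design
  d <- model.frame(m)
  if (random_kind == "slope") {
    Xre <- model.matrix(as.formula(paste0("~", job$slope_factor)), data = d)
  } else {
    Xre <- matrix(1, nrow = nrow(d), ncol = 1)
  }
  var_random <- mean(rowSums((Xre %*% Sig) * Xre))
  conv <- isTRUE(m$fit$convergence == 0) && all(is.finite(V))
  list(
    beta = as.numeric(beta),
    beta_names = names(beta),
    vcov = as.numeric(V),
    re_cov = as.numeric(Sig),
    re_names = rownames(Sig),
    var_random = var_random,
    sigma = sigma(m),
    loglik = as.numeric(logLik(m)),
    converged = conv,
    singular = any(diag(Sig) < 1e-8),
    random = random_kind
  )
}

for (i in seq_along(jobs)) {
  job <- jobs[[i]]
  d <- read.csv(job$csv, check.names = FALSE)
  d[[job$group]] <- factor(d[[job$group]])
  if (!is.null(job$slope_factor) && job$slope_factor %in% names(d)) {
    d[[job$slope_factor]] <- factor(d[[job$slope_factor]],
                                    levels = unlist(job$slope_levels))
  }
  random_kind <- job$random
  res <- NULL
  if (random_kind == "slope") {
    res <- tryCatch({
      m <- fit_one(d, job, "slope")
      r <- extract(m, job, "slope")
      if (!r$converged || r$singular) NULL else r
    }, error = function(e) NULL, warning = function(w) NULL)
    if (is.null(res)) random_kind <- "intercept"  # singular fallback
  }
  if (is.null(res)) {
    res <- tryCatch({
      m <- fit_one(d, job, "intercept")
      extract(m, job, "intercept")
    }, error = function(e) list(error = conditionMessage(e)))
  }
  res$fell_back <- !identical(random_kind, job$random)
  out[[i]] <- res
}

writeLines(toJSON(out, digits = NA, auto_unbox = TRUE, null = "null"),
           args[[2]])
"""


def run_glmm_jobs(jobs: list[dict], dataframes: list, timeout_s: float = 1800.0) -> list[dict]:
    """Fit one GLMM per (job, dataframe) pair in a single R session.

    Each job dict needs: response, family ('gaussian'|'gamma'|'negbin'),
    x_cols (fixed-design column names present in the dataframe), group,
    random ('intercept'|'slope'), and for slope models slope_factor plus
    slope_levels.  Returns one result dict per job.
    """
    if len(jobs) != len(dataframes):
        raise ValueError("one dataframe per job required")
    with tempfile.TemporaryDirectory(prefix="camoquant_glmm_") as tmp:
        tmpdir = Path(tmp)
        prepared = []
        for i, (job, df) in enumerate(zip(jobs, dataframes)):
            csv = tmpdir / f"data_{i}.csv"
            df.to_csv(csv, index=False)
            prepared.append({**job, "csv": str(csv)})
        script = tmpdir / "fit.R"
        script.write_text(_R_SCRIPT)
        jobs_json = tmpdir / "jobs.json"
        jobs_json.write_text(json.dumps(prepared))
        out_json = tmpdir / "out.json"
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(jobs_json), str(out_json)],
            capture_output=True, text=True, timeout=timeout_s,
        )
        if proc.returncode != 0 or not out_json.exists():
            raise RGlmmError(
                f"Rscript/glmmTMB failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        results = json.loads(out_json.read_text())
    for i, res in enumerate(results):
        if "error" in res:
            raise RGlmmError(f"glmmTMB fit {i} failed: {res['error']}")
    return results
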