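#!/usr/bin/env Rscript
# Batched binomial GLMM fitting backend.
# Usage: Rscript lme4_fit.R <workdir>
# Reads <workdir>/specs.json (list of {data, formula, relevel, factors}),
# fits each model with lme4::glmer, and writes <workdir>/results.json with
# fixed effects, single-term-deletion LRT p-values and variance components.

suppressMessages(library(lme4))
suppressMessages(library(jsonlite))

args <- commandArgs(trailingOnly = TRUE)
workdir <- args[1]
specs <- fromJSON(file.path(workdir, "specs.json"), simplifyVector = FALSE)

fit_one <- function(sp) {
  dat <- read.csv(file.path(workdir, sp$data), stringsAsFactors = FALSE)
  if (!is.null(sp$factors)) {
    for (col in sp$factors) dat[[col]] <- factor(dat[[col]])
  }
  if (!is.null(sp$relevel)) {
    for (col in names(sp$relevel)) {
      dat[[col]] <- relevel(factor(dat[[col]]), ref = sp$relevel[[col]])
    }
  }
  msgs <- character(0)
  fit <- withCallingHandlers(
    glmer(as.formula(sp$formula), data = dat, family = binomial),
    warning = function(w) {
      msgs <<- c(msgs, conditionMessage(w))
      invokeRestart("muffleWarning")
    }
  )
  co <- summary(fit)$coefficients
  drop_p <- list()
  d1 <- NULL
  if (is.null(sp$no_drop1) || !sp$no_drop1) {
    d1 <- tryCatch(drop1(fit, test = "Chisq"), error = function(e) NULL)
  }
  if (!is.null(d1)) {
    for (r in rownames(d1)) {
      if (r != "<none>") drop_p[[r]] <- unname(d1[r, "Pr(Chi)"])
    }
  }
  vc <- as.data.frame(VarCorr(fit))
  conv_msgs <- unlist(fit@optinfo$conv$lme4$messages)
  list(
    ok = TRUE,
    n = nrow(dat),
    converged = is.null(conv_msgs),
    messages = as.list(c(msgs, conv_msgs)),
    terms = rownames(co),
    estimate = unname(co[, 1]),
    se = unname(co[, 2]),
    z = unname(co[, 3]),
    p = unname(co[, 4]),
    drop1 = drop_p,
    vc_group = as.list(vc$grp),
    vc_var = as.list(vc$vcov)
  )
}

results <- lapply(specs, function(sp) {
  tryCatch(fit_one(sp), error = function(e) list(ok = FALSE, error = conditionMessage(e)))
})

write(
  toJSON(results, auto_unbox = TRUE, digits = 12, na = "null", null = "null"),
  file.path(workdir, "results.json")
)
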