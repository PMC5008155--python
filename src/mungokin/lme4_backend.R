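# Mixed-model fitting backend: ML (g)lmer fits with backward elimination by
# likelihood-ratio chi-square, driven by a JSON config. Invoked as
#   Rscript lme4_backend.R <config.json>
# and writes a JSON result to cfg$out. One result per replicate when the
# data carries a replicate column.

suppressMessages({
  library(lme4)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
cfg <- fromJSON(args[[1]], simplifyVector = TRUE)
dat <- read.csv(cfg$data, stringsAsFactors = FALSE)

fit_one <- function(d) {
  for (f in cfg$random) d[[f]] <- factor(d[[f]])
  fixed <- as.character(cfg$fixed)
  ranpart <- paste(sprintf("(1|%s)", cfg$random), collapse = " + ")
  n_warn <- 0L

  mkform <- function(terms) {
    rhs <- if (length(terms)) paste(c(terms, ranpart), collapse = " + ") else ranpart
    as.formula(paste(cfg$response, "~", rhs))
  }
  fitfun <- function(terms) {
    form <- mkform(terms)
    withCallingHandlers(
      {
        if (cfg$family == "gaussian") {
          lmer(form, data = d, REML = FALSE)
        } else {
          glmer(form, data = d, family = binomial,
                control = glmerControl(calc.derivs = FALSE))
        }
      },
      warning = function(w) {
        n_warn <<- n_warn + 1L
        invokeRestart("muffleWarning")
      },
      message = function(m) invokeRestart("muffleMessage")
    )
  }
  lrt <- function(small, big) {
    chi <- max(0, 2 * (as.numeric(logLik(big)) - as.numeric(logLik(small))))
    c(chi, pchisq(chi, df = 1, lower.tail = FALSE))
  }

  current_terms <- fixed
  current <- fitfun(current_terms)
  if (isTRUE(cfg$simplify)) {
    repeat {
      if (!length(current_terms)) break
      ps <- vapply(current_terms, function(t) {
        lrt(fitfun(setdiff(current_terms, t)), current)[2]
      }, numeric(1))
      worst <- which.max(ps)
      if (ps[worst] > cfg$alpha) {
        current_terms <- setdiff(current_terms, current_terms[worst])
        current <- fitfun(current_terms)
      } else {
        break
      }
    }
  }
  minimal <- current

  terms_out <- list()
  if (isTRUE(cfg$estimates_only)) {
    # skip the per-term LRTs: report effect sizes/SEs from the fitted model
    co <- summary(minimal)$coefficients
    for (t in fixed) {
      terms_out[[t]] <- list(
        estimate = unname(co[t, 1]), se = unname(co[t, 2]),
        chisq = NA, p = NA, in_minimal = (t %in% current_terms)
      )
    }
    return(list(
      terms = terms_out,
      minimal_terms = as.list(current_terms),
      intercept = unname(co["(Intercept)", 1]),
      intercept_se = unname(co["(Intercept)", 2]),
      n_obs = nrow(d),
      singular = isSingular(minimal),
      converged = (n_warn == 0L),
      n_warnings = n_warn
    ))
  }
  for (t in fixed) {
    if (t %in% current_terms) {
      s <- lrt(fitfun(setdiff(current_terms, t)), minimal)
      co <- summary(minimal)$coefficients
      inmin <- TRUE
    } else {
      # dropped terms are individually put back into the minimal model
      aug <- fitfun(c(current_terms, t))
      s <- lrt(minimal, aug)
      co <- summary(aug)$coefficients
      inmin <- FALSE
    }
    terms_out[[t]] <- list(
      estimate = unname(co[t, 1]), se = unname(co[t, 2]),
      chisq = s[1], p = s[2], in_minimal = inmin
    )
  }
  co_min <- summary(minimal)$coefficients
  list(
    terms = terms_out,
    minimal_terms = as.list(current_terms),
    intercept = unname(co_min["(Intercept)", 1]),
    intercept_se = unname(co_min["(Intercept)", 2]),
    n_obs = nrow(d),
    singular = isSingular(minimal),
    converged = (n_warn == 0L),
    n_warnings = n_warn
  )
}

if (!is.null(cfg$replicate_col) && cfg$replicate_col %in% names(dat)) {
  reps <- sort(unique(dat[[cfg$replicate_col]]))
  results <- lapply(reps, function(r) {
    res <- tryCatch(fit_one(dat[dat[[cfg$replicate_col]] == r, ]),
                    error = function(e) list(error = conditionMessage(e)))
    res$replicate <- r
    res
  })
} else {
  results <- list(fit_one(dat))
}

write_json(results, cfg$out, auto_unbox = TRUE, digits = NA, null = "null")
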