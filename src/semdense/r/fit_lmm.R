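# Fit the crossed-random-effects model for the lexical decision analysis.
# Driven by the Python bridge: Rscript fit_lmm.R <config.json>
# The config names the data CSV, formula, factor codings, optional named
# contrast vectors (tested with Satterthwaite df), an optional replicate
# column for batch fitting, and the output JSON path.

suppressMessages({
  library(lme4)
  library(lmerTest)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 1) stop("usage: Rscript fit_lmm.R config.json")
cfg <- fromJSON(args[[1]], simplifyVector = TRUE)

dat <- utils::read.csv(cfg$data, stringsAsFactors = FALSE)

prep <- function(d) {
  d$group <- factor(d$group, levels = cfg$group_levels)
  d$type <- factor(d$type, levels = cfg$type_levels)
  if (identical(cfg$coding, "sum")) {
    contrasts(d$group) <- contr.sum(length(cfg$group_levels))
    contrasts(d$type) <- contr.sum(length(cfg$type_levels))
  } else {
    contrasts(d$group) <- contr.treatment(length(cfg$group_levels))
    contrasts(d$type) <- contr.treatment(length(cfg$type_levels))
  }
  d$participant <- factor(d$participant)
  d$stimulus <- factor(d$stimulus)
  d
}

fit_one <- function(d, return_pred) {
  X <- model.matrix(lme4::nobars(as.formula(cfg$formula)), d)
  qrX <- qr(X)
  if (qrX$rank < ncol(X)) {
    aliased <- colnames(X)[qrX$pivot[(qrX$rank + 1):ncol(X)]]
    stop(sprintf("rank-deficient fixed design; aliased terms: %s",
                 paste(aliased, collapse = ", ")))
  }
  msgs <- character(0)
  m <- withCallingHandlers(
    lmerTest::lmer(as.formula(cfg$formula), data = d, REML = isTRUE(cfg$reml)),
    warning = function(w) {
      msgs <<- c(msgs, conditionMessage(w))
      invokeRestart("muffleWarning")
    },
    message = function(mm) {
      msgs <<- c(msgs, conditionMessage(mm))
      invokeRestart("muffleMessage")
    }
  )
  a <- anova(m, type = 3, ddf = cfg$ddf)
  vc <- as.data.frame(VarCorr(m))
  lme4_msgs <- unlist(m@optinfo$conv$lme4$messages)
  real_problems <- lme4_msgs[!grepl("singular", lme4_msgs, ignore.case = TRUE)]
  out <- list(
    coef_names = names(fixef(m)),
    coef = unname(fixef(m)),
    vcov = unname(as.matrix(vcov(m))),
    anova = list(
      terms = rownames(a),
      sum_sq = a[["Sum Sq"]],
      mean_sq = a[["Mean Sq"]],
      num_df = a[["NumDF"]],
      den_df = a[["DenDF"]],
      f_value = a[["F value"]],
      p_value = a[["Pr(>F)"]]
    ),
    varcorr = list(
      grp = vc$grp, var1 = vc$var1, var2 = vc$var2,
      vcov = vc$vcov, sdcor = vc$sdcor
    ),
    sigma = sigma(m),
    n_obs = nobs(m),
    n_participants = length(levels(droplevels(d$participant))),
    n_stimuli = length(levels(droplevels(d$stimulus))),
    reml_criterion = as.numeric(REMLcrit(m)),
    singular = isSingular(m),
    converged = (m@optinfo$conv$opt == 0) && (length(real_problems) == 0),
    messages = as.list(msgs)
  )
  if (isTRUE(return_pred)) {
    out$fitted <- unname(fitted(m))
    out$fixed_pred <- unname(predict(m, re.form = NA))
  }
  if (!is.null(cfg$contrasts) && length(cfg$contrasts) > 0) {
    ct <- list()
    for (nm in names(cfg$contrasts)) {
      w <- cfg$contrasts[[nm]]
      L <- setNames(rep(0, length(fixef(m))), names(fixef(m)))
      if (!all(names(w) %in% names(L))) {
        stop(sprintf("contrast '%s' refers to unknown coefficients: %s", nm,
                     paste(setdiff(names(w), names(L)), collapse = ", ")))
      }
      L[names(w)] <- unlist(w)
      res <- lmerTest::contest1D(m, unname(L), ddf = cfg$ddf)
      ct[[nm]] <- list(
        estimate = res[["Estimate"]], se = res[["Std. Error"]],
        df = res[["df"]], t_value = res[["t value"]], p_value = res[["Pr(>|t|)"]]
      )
    }
    out$contrasts <- ct
  }
  if (isTRUE(cfg$emmeans_type)) {
    suppressMessages(library(emmeans))
    emm <- emmeans(m, ~type, lmer.df = "asymptotic")
    pr <- summary(pairs(emm, adjust = "none"))
    out$emmeans_type <- list(
      contrast = as.character(pr$contrast), estimate = pr$estimate,
      se = pr$SE, z = pr$z.ratio, p_value = pr$p.value
    )
  }
  out
}

return_pred <- isTRUE(cfg$return_pred)
if (!is.null(cfg$replicate_col) && cfg$replicate_col %in% names(dat)) {
  reps <- sort(unique(dat[[cfg$replicate_col]]))
  results <- vector("list", length(reps))
  for (i in seq_along(reps)) {
    dd <- prep(droplevels(dat[dat[[cfg$replicate_col]] == reps[i], ]))
    results[[i]] <- tryCatch(
      c(list(replicate = reps[i]), fit_one(dd, return_pred)),
      error = function(e) list(replicate = reps[i], error = conditionMessage(e))
    )
  }
  write_json(results, cfg$out, digits = NA, auto_unbox = TRUE, na = "null")
} else {
  write_json(fit_one(prep(dat), return_pred), cfg$out,
             digits = NA, auto_unbox = TRUE, na = "null")
}
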