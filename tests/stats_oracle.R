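#!/usr/bin/env Rscript
# Independent reference implementation for the statistical battery.
# Reads a JSON list of datasets; writes a JSON list of test results.
suppressMessages(library(jsonlite))
args <- commandArgs(trailingOnly = TRUE)
payload <- fromJSON(args[1], simplifyVector = FALSE)
out <- list()
for (i in seq_along(payload$datasets)) {
  d <- payload$datasets[[i]]
  x <- unlist(d$x); y <- unlist(d$y)
  xp <- unlist(d$xp); yp <- unlist(d$yp)
  g <- unlist(d$g)

  tt <- t.test(x, y, var.equal = TRUE)
  wt <- wilcox.test(x, y, correct = FALSE, exact = FALSE)
  sw <- shapiro.test(x)
  ct <- cor.test(xp, yp)
  fit <- lm(yp ~ xp)
  sl <- summary(fit)$coefficients["xp", ]
  gf <- factor(g)
  fit2 <- lm(yp ~ gf * xp)
  an <- anova(fit2)
  out[[i]] <- list(
    t_stat = unname(tt$statistic), t_p = tt$p.value,
    u_stat = unname(wt$statistic), u_p = wt$p.value,
    sw_stat = unname(sw$statistic), sw_p = sw$p.value,
    r = unname(ct$estimate), r_p = ct$p.value,
    slope = unname(sl["Estimate"]), slope_p = unname(sl["Pr(>|t|)"]),
    f_inter = an["gf:xp", "F value"], f_inter_p = an["gf:xp", "Pr(>F)"]
  )
}
write_json(out, args[2], digits = NA, auto_unbox = TRUE)
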