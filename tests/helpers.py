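"""Shared helpers for the test suite."""
import dataclasses

from wmcea.params import DrugPrice, DrugPriceTable


def scale_all_prices(params, alpha):
    """Scale every unit price, tariff and monitoring bundle by ``alpha``."""
    prices = DrugPriceTable(
        prices={
            d: DrugPrice(p.unit_mg, p.unit_cost_eur * alpha)
            for d, p in params.prices.prices.items()
        }
    )
    tariffs = dataclasses.replace(
        params.tariffs,
        tariffs={
            k: dataclasses.replace(t, tariff_eur=t.tariff_eur * alpha)
            for k, t in params.tariffs.tariffs.items()
        },
    )
    monitoring = dataclasses.replace(
        params.monitoring_costs,
        pre_progression_ibrutinib=params.monitoring_costs.pre_progression_ibrutinib * alpha,
        pre_progression_ctp=params.monitoring_costs.pre_progression_ctp * alpha,
        subsequent=params.monitoring_costs.subsequent * alpha,
        bsc=params.monitoring_costs.bsc * alpha,
    )
    return dataclasses.replace(
        params, prices=prices, tariffs=tariffs, monitoring_costs=monitoring
    )
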