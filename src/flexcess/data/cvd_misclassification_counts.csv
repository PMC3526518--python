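year_band,age_band,at_risk,observed,expected,ed_printed,p10_printed,p15_printed,p20_printed
1973-1977,<=49,3339,35,11.9,23.1,6.6,10.0,13.1
1973-1977,50-59,3713,127,42.4,84.6,6.7,10.0,13.3
1973-1977,60-69,4522,600,205.3,394.7,6.6,9.9,13.2
1973-1977,70-79,4009,1313,621.8,691.2,5.3,7.9,10.5
1978-1982,<=49,3447,28,10.5,17.5,6.4,9.3,12.5
1978-1982,50-59,3750,127,42.1,84.9,6.7,10.0,13.4
1978-1982,60-69,4933,607,219.4,387.6,6.4,9.6,12.8
1978-1982,70-79,4898,1592,733.7,859.3,5.4,8.1,10.8
1983-1987,<=49,3894,29,9.5,19.5,6.9,10.0,13.4
1983-1987,50-59,3463,122,33.5,88.5,7.3,10.9,14.5
1983-1987,60-69,5055,571,203.1,367.9,6.4,9.7,12.9
1983-1987,70-79,5155,1554,696.3,857.7,5.5,8.3,11.0
1988-1992,<=49,4640,44,12.2,31.8,7.3,10.9,14.5
1988-1992,50-59,4308,106,40.5,65.5,6.2,9.2,12.4
1988-1992,60-69,6200,598,240.6,357.4,6.0,9.0,12.0
1988-1992,70-79,5329,1485,630.9,854.1,5.8,8.6,11.5
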