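id,age,pH,BDecf,pCO2,BE,apgar1,apgar5,dev_type
2001,30,7.03,22.5,22.8,-23.7,10,10,2
2002,39,7.27,3.75,6.5,-4.5,7,4,2
2003,25,6.96,16.96,7.2,-19,6,8,2
2004,34,6.95,11.44,11.6,-15.3,6,8,2
2005,31,7.25,3.47,7,-5.5,10,10,2
2006,32,7.29,NaN,NaN,NaN,10,10,2
2007,27,7.04,20.4,23.8,-21.8,10,10,2
2008,26,6.98,13.43,9.3,-16.7,5,7,2
2009,21,6.96,20.34,5.4,-23,10,10,2
2010,19,7.3,-0.48,7.2,-1.5,10,10,2
2011,37,7.01,12.1,9.2,-14.8,3,7,2
2012,26,7.29,-0.44,7.4,-1.4,9,9,2
2013,27,6.85,22.63,6.4,-25.3,8,8,2
2014,34,7.3,2.28,6,-3.2,10,10,2
2015,29,7.33,4.15,5.3,-5.1,9,10,2
2016,38,7.27,1.88,7.1,-3.8,9,10,2
2017,34,7.32,-0.16,6.7,-2,10,10,2
2018,30,7.31,3.93,5.7,-5,10,10,2
2019,31,7.29,4.13,6,-5.6,9,9,2
2020,28,7.15,3.09,9.6,-5.8,4,7,2
2021,28,7.3,0.19,7,-2.2,9,10,2
2022,31,7.28,-0.38,7.6,-1.6,9,10,2
2023,28,6.98,14.49,8.7,-17.4,6,8,2
2024,39,7.01,7.14,12.1,-10.9,2,4,2
2025,29,6.99,12.61,9.5,-16,8,8,2
2026,32,7.23,-0.13,8.7,-2.1,10,10,2
2027,26,7.31,1.88,6.3,-3.2,9,10,2
2028,36,7.18,4.82,8.1,-7.2,8,9,2
2029,34,7.28,1.22,7.1,-3.4,10,10,2
2030,42,7.04,26.1,10.7,-26.8,10,10,2
2031,26,7.29,1.52,6.8,-2.9,9,9,2
2032,35,7.26,3.14,6.9,-4.7,9,10,2
2033,26,7.39,0.86,5.2,-1.5,9,9,2
2034,34,7.34,NaN,NaN,NaN,9,9,2
2035,27,7.26,2.23,7.2,-4.3,8,9,2
2036,34,7.29,2.5,6.5,-3.7,5,7,2
2037,29,7.25,1.09,7.8,-3,9,10,2
2038,27,7.36,3.5,5,-4,5,8,2
2039,29,7.32,-0.51,6.8,-0.5,9,10,2
2040,23,7.23,5.27,6.8,-7,2,6,2
2041,32,7.37,3.69,4.8,-3.1,9,9,2
2042,27,7.33,-0.5,6.6,-0.8,9,10,2
2043,26,7.08,10.92,7.9,-13.3,8,9,2
2044,27,7.02,9.13,10.6,-12.3,8,8,2
2045,32,7.03,8.91,10.4,-12.2,7,9,2
2046,19,7.01,NaN,NaN,NaN,5,7,2
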